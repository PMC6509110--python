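# sheetloc

Analysis pipeline for **Bessel-lightsheet 3D single-molecule localization
microscopy** (SMLM): an instrument family that scans a thin Bessel-beam light
sheet through a sample at an oblique angle (32.5° to the coverslip), excites
spontaneously blinking fluorophores plane by plane, and reconstructs
super-resolved 3D images from millions of single-molecule fits with
astigmatism-encoded depth.

The package is for microscopists and image analysts who need the full
computational chain around such an instrument:

* **optics** — scalar annular-pupil model of the excitation beam. The sheet
  thickness is the FWHM of the central lobe of
  I(r) = |∫_{NA_in}^{NA_out} J₀(2π·NA·r/λ)·NA dNA|²; at the reference
  configuration (λ = 637 nm, NA 0.42–0.50) this is ≈ 0.5 µm. Also
  acquisition-plan timing and excitation power-density arithmetic.
* **simulate** — seeded synthetic acquisitions: emitters on filaments, nuclear
  pore rings, or fiducial beads; exact frame-clock sampling of the two-state
  blinking chain (duty cycle k_on/(k_on+k_off)); sheet-weighted excitation with
  optional side lobes; astigmatic PSF; sCMOS shot/read noise at 102 nm pixels.
* **calibration** — the astigmatic defocus model
  σᵢ(z) = σ₀ᵢ√(1 + u² + Aᵢu³ + Bᵢu⁴), u = (z−cᵢ)/dᵢ, fitted per axis to bead
  z-stacks and inverted by minimizing
  D(z) = (√σₓ−√σₓᶜᵃˡ(z))² + (√σ_y−√σ_yᶜᵃˡ(z))².
* **localize** — DoG detection, integrated elliptical-Gaussian fitting,
  Thompson–Larson–Webb theoretical uncertainty
  σ_loc² = σ²/N + a²/12N + 8πσ⁴b²/a²N², z assignment, quality filtering.
* **postprocess** — fiducial-track and cross-correlation drift correction,
  deskew of sheet-frame coordinates to coverslip coordinates, per-plane time
  series transposition, uncertainty-weighted Gaussian rendering, temporal
  color coding.
* **frc** — Fourier ring correlation resolution (1/7 threshold) and the
  resolution-versus-accumulated-volumes curve.
* **npc** — nuclear pore complex particle averaging: 10 nm binning, candidate
  masks (fill → 3×3 dilation → [250, 300] px² area window), per-candidate
  donut fits A·exp(−(r−r₀)²/2σ_r²)+c, KDE centering, top-50 overlay, and pore
  diameter 2·r₀.
* **io / cli** — ThunderSTORM-dialect CSV tables, TIFF stacks, validated YAML
  configuration, and a `sheetloc` command-line tool.

## Worked example

```python
import sheetloc as sl

# Optical sectioning of the excitation sheet
spec = sl.BesselBeamSpec(wavelength_nm=637.0, na_inner=0.42, na_outer=0.50)
print(f"sheet FWHM: {sl.sheet_thickness_fwhm(spec):.1f} nm")
plan = sl.acquisition_plan(n_planes=151, exposure_s=0.020)
print(f"volume time: {plan.total_time_s:.2f} s at {plan.plane_rate_hz:.0f} planes/s")

# Nuclear-pore particle averaging on synthetic ground truth
pores = sl.make_ground_truth(
    "npc_ring",
    {"n_pores": 100, "ring_diameter_nm": 100.0, "sites_per_ring": 8,
     "labeling_efficiency": 0.8, "extent_nm": (20000, 20000)},
    seed=0,
)
table = sl.simulate_localizations(
    pores, sl.BlinkingModel(k_on=0.5), n_frames=3000, exposure_s=0.020,
    precision_nm=15.0, seed=1,
)
print(f"{len(table)} localizations from {len(pores)} labeled sites")
result = sl.average_pipeline(table)
print(f"{len(result['candidates'])} pore candidates pass the area window")
print(f"averaged pore diameter: {result['diameter_nm']:.1f} nm")
```

prints

```
sheet FWHM: 494.8 nm
volume time: 3.02 s at 50 planes/s
18845 localizations from 641 labeled sites
35 pore candidates pass the area window
averaged pore diameter: 91.8 nm
```

The sheet FWHM rounds to the 0.5 µm optical-sectioning thickness of the
reference instrument; 151 planes at 20 ms sweep one volume in 3.02 s.  The
averaged diameter reads ≈ 92 nm for 100 nm rings observed at 15 nm
localization precision — the small inward bias of donut-fitting a smeared
ring (≈ 2σ²/r₀; see `docs/methods.md`).

The same chain is scriptable from the shell:

```sh
sheetloc simulate --seed 1 --out run/
sheetloc localize --stack run/stack_vol0000.tif --out run/locs.csv
sheetloc drift --locs run/locs.csv --method xcorr --out run/locs_corrected.csv
sheetloc deskew --locs run/locs_corrected.csv --out run/locs_deskewed.csv
sheetloc frc --locs run/locs_deskewed.csv --pixel 10
sheetloc npc --locs run/locs_deskewed.csv --out run/npc/
```

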