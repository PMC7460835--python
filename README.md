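# leafseal

Analysis pipeline for the **self-sealing kinematics, morphometry and
biomechanics of succulent *Delosperma* leaves**.

Leaves of *Delosperma cooperi* and *Delosperma ecklonis* react to a
circumferential (ring) incision by contracting along the leaf axis until
the wound edges touch — a rapid, hydraulically driven self-sealing
response that precedes slower self-healing. The experimental observable
is a set of 17 marker points (5 painted, 12 virtual) tracked along the
leaf midline in time-lapse images (1/6 Hz for one hour). `leafseal`
turns such marker trajectories into segment-wise contraction measures,
runs the rank-based factorial statistics used to compare species and
humidity levels, and computes the morphometric and biomechanical derived
quantities (tissue thicknesses, shrinkage, turgor-based parenchyma
moduli, interspecific ratio tables).

## The core quantities

For each leaf segment *i* (apex = p1–p5, incision = p5–p9, base =
p9–p17) with length *Lᵢ(t)* — Y-axis marker spacing for straight leaves,
arc length along a per-frame polynomial midline fit for recurved
leaves — the pipeline computes

- **absolute contraction** εᵢ(t) = (Lᵢ(t) − Lᵢ(t₀)) / Lᵢ(t₀)
- **relative contraction** εᵢ*(t) = εᵢ(t) · Lᵢ(t) / L_total(t)

(negative values mean shortening). Per-leaf endpoint summaries feed a
**Scheirer–Ray–Hare test** — a two-way ANOVA on mid-ranks where each
effect's H = SS_effect / MS_total is referred to a χ² distribution —
with Bonferroni-adjusted pairwise Wilcoxon rank-sum post-hocs.

On the mechanics side, tensile stress–strain traces yield the elastic
modulus *E* (slope of the best linear region), tensile strength σ_max
and Poisson's ratio ν; parenchyma stiffness is derived from cell
geometry and turgor *P* through a linear-in-turgor relation
E = 4·E_cw·(t_cw/d_c) + (27/8)·P (see `docs/methods.md` for the
provenance of the coefficients).

A seeded synthetic-data generator (`leafseal.synthetic`) emulates the
whole experiment — straight vs. recurved midlines, segment-specific
saturating contraction L(t) = L₀(1 + ε∞(1 − e^(−t/τ))), Gaussian
tracking noise, 2 (species) × 2 (relative humidity) cohorts — so every
downstream stage is testable without the original recordings.

## Worked example

```python
from leafseal.synthetic import LeafSimConfig, simulate_leaf
from leafseal.kinematics import ContractionSeries, endpoint_summary

cfg = LeafSimConfig(
    shape_profile="recurved", leaf_length_mm=27.4, curvature_radius_mm=40.0,
    segment_plateaus={"apex": -0.03, "incision": -0.05, "base": -0.03},
    noise_sd_mm=0.02, seed=7,
)
series = ContractionSeries.from_track(simulate_leaf(cfg), mode="arc", degree=3)
for seg, eps in endpoint_summary(series, window_frames=5).items():
    print(f"{seg:9s} eps_hat = {eps:+.4f}")
```

```
apex      eps_hat = -0.0299
incision  eps_hat = -0.0540
base      eps_hat = -0.0305
```

The recovered endpoint contractions sit on the configured plateaus
(−0.03, −0.05, −0.03, each scaled by 1 − e⁻⁶ ≈ 0.9975) to within the
0.02 mm tracking noise — the incision region of this recurved leaf
shortened by about 5.4 %. The turgor-based tissue stiffness works from
published median cell measurements:

```python
from leafseal.biomechanics import nilsson_parenchyma_modulus
from leafseal.morphometry import CellGeometry

E = nilsson_parenchyma_modulus(CellGeometry(d_c_um=92.00, t_cw_um=0.42),
                               P_mpa=0.04, nu=0.29, E_cw_mpa=5.00)
print(f"hydrenchyma modulus = {E:.2f} MPa")
```

```
hydrenchyma modulus = 0.23 MPa
```

A full run (simulate → contract → compare → tables → report) from the
shell:

```sh
leafseal run-all --seed 1 --out run
```

which writes tidy per-stage CSVs, a statistics report with significance
stars, and the interspecific comparison tables under `run/`.

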