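# pseudopod-ad

Adhesive-dynamics simulation of a pseudopod-bearing neutrophil tethering
on a P-selectin-coated vessel wall under shear flow.

During inflammation, neutrophils are captured from the bloodstream by
P-selectin on the endothelium binding PSGL-1 on the cell surface.
Activated neutrophils often carry a stiff, actin-supported pseudopod,
and a circulating population of pseudopod-bearing cells exists whose
capture mechanics differ from the classical sphere. This package is for
cell-adhesion biophysicists who want a transparent, fully scriptable
model of that process: it simulates the rigid-body Stokes dynamics of a
sphere-plus-Gaussian-pseudopod cell above a plane no-slip wall, coupled
to Monte-Carlo P-selectin/PSGL-1 bond kinetics, and reduces the
trajectories to the standard behavioural taxonomy (firm adhesion on
first contact, tethering followed by firm adhesion, tethering only, no
bonds) with tether lifetime, rolling distance, perpendicular
displacement, bond-count and contact-area statistics.

## Model core

- **Geometry** — star-shaped surface r(θ) = a·(1 + Λ·e^(−θ²/2w²)) with
  Λ = 1.9, meshed into 384 nine-node quadrilaterals and volume-normalised
  to the 4-µm equal-volume sphere; 25,100 PSGL-1 receptors allocated to
  elements proportionally to area (largest-remainder rounding).
- **Hydrodynamics** — quasi-static mobility problem at zero Reynolds
  number, solved by single-layer boundary-integral collocation with the
  image-system Green's function for a point force above a no-slip wall;
  ambient flow u = γ̇ z x̂.
- **Kinetics** — bond formation k_f = k_f⁰·exp(σ|x_b−l_b|(γ−½|x_b−l_b|)/k_BT);
  two-pathway dissociation k_r = k_N/(1+Φ) + Φ k_I(f)/(1+Φ) with
  Φ(f) = Φ₀·e^(γ′f/k_BT) and k_I(f) = k_I⁰·e^(y_I f/k_BT); per-step
  Bernoulli draws P = 1 − e^(−kΔt).
- **Coupling** — per step: contact detection → Monte-Carlo bond events →
  load assembly (bond springs + steric wall repulsion) → mobility solve →
  rigid-body update (quaternion exponential).

See `docs/methods.md` for assumptions, parameters, units (µm, s, fN)
and numerical choices.

## Worked example

Run ten reduced-profile simulations at shear rate 500 s⁻¹ with a fast
on-rate (20 s⁻¹) and classify each trajectory:

```python
import dataclasses
from pseudopod_ad import reduced_profile, run, summarize

for seed in range(1, 11):
    cfg = reduced_profile(shear_rate=500.0, seed=seed)
    cfg = cfg.replace(kinetics=dataclasses.replace(cfg.kinetics, kf2D0=20.0))
    traj = run(cfg)
    s = summarize(traj)
    print(seed, s.category, f"x_final={traj.centroid[-1,0]:.1f} um",
          f"t_final={traj.final_time*1e3:.1f} ms",
          f"max_bonds={traj.bond_counts.max()}")
```

Output from this exact loop (first five seeds shown):

```
1 firm_first_contact x_final=21.6 um t_final=21.1 ms max_bonds=40
2 firm_first_contact x_final=28.3 um t_final=21.9 ms max_bonds=40
3 firm_first_contact x_final=13.7 um t_final=14.2 ms max_bonds=40
4 firm_first_contact x_final=23.6 um t_final=19.9 ms max_bonds=40
5 firm_first_contact x_final=22.1 um t_final=16.4 ms max_bonds=40
```

All ten seeds arrest firmly on first contact: the pseudopod tip binds
the wall within a few ms of first touch, the body swings around the
tethered tip (perpendicular y-excursions up to ≈3.9 µm), and the bond
cluster grows to the cap while the cell stalls at x ≈ 14–28 µm at
t ≈ 13–22 ms — the signature of firm adhesion at a high bond-formation
rate. At k_f⁰ = 1 s⁻¹ the same seeds instead produce brief tethers
(1–5 ms episodes of 1–4 bonds) that release and let the cell escape
downstream, and at shear 100 s⁻¹ every run again arrests on first
contact.

The CLI wraps the same machinery:

```bash
pseudopod-ad run --profile reduced --seed 1 --out run1/
pseudopod-ad sweep --variable kf2D0 --values 1,5,10,15,20 --out sweep/
pseudopod-ad orientation-grid --out grid/
pseudopod-ad analyze run1/
```

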