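# nanodomain

Tools for studying how a membrane receptor (EGFR) partitions between
tetraspanin and clathrin nanodomains on the plasma membrane: an agent-based
lattice Monte-Carlo simulator of receptor diffusion with ligand-state–
dependent energy barriers, ensemble confinement statistics, an equilibrium
two-site ligand-occupancy model, and puncta-detection / colocalization
analyses with matched synthetic-data generators. It is written for
quantitative cell biologists and modellers who want a tested, reproducible
implementation of this class of nanodomain-confinement analysis, driven
entirely by simulation — no experimental data are required.

## The model

A single receptor random-walks on an `n × n` periodic square lattice
(spacing Δx = 2 nm, box 0.2 μm) with timestep

    Δt = Δx² / (4D),   D = 0.2 μm²/s  ⇒  Δt = 5·10⁻⁶ s.

The membrane carries 10 tetraspanin and 10 clathrin discs (radius 5.6 nm,
area ≈ 100 nm², non-overlapping, re-placed randomly for every trajectory).
Each timestep the receptor attempts a move to one of the four neighbours; a
move that crosses a domain boundary succeeds with the Metropolis
probability exp(−ΔE/k_BT). Unliganded receptors face barriers only at
tetraspanin boundaries (ΔE_entry = 11.5 k_BT, ΔE_exit = 13 k_BT), liganded
receptors only at clathrin boundaries (1 and 4.5 k_BT). Ligand binding is
possible only inside tetraspanin domains (rate k_bind, swept to emulate
ligand concentration, with the tetraspanin barriers lifted instantly on
binding), and liganded receptors inside clathrin domains are removed from
the membrane at 0.05 s⁻¹ (endocytosis). Ensemble confinement fractions
weight each trajectory by its membrane lifetime, mirroring how long a
receptor is experimentally observable.

Two analytic anchors fall out of the barrier pair: unliganded receptors
equilibrate to an occupancy density exp(13 − 11.5) = e^1.5 ≈ 4.48 inside
tetraspanin domains relative to outside, and the mean first-passage time
into a tetraspanin domain is of order a minute (≈ 83 s).

The occupancy model treats surface EGFR as a mixture of a high-affinity
minority (Kd ≈ 0.1 nM, 10% of sites) and a low-affinity majority
(Kd 2–6 nM, 90%), with occupancy θ(c) = Σᵢ fᵢ·c/(c + Kdᵢ) and ng/mL → nM
conversion via the 6045 Da mass of mature human EGF.

## Worked example

```python
import nanodomain as nd

stats = nd.first_entry_times(nd.default_params(), n_reps=25, seed=1)
print(f"mean entry time {stats.mean:.1f} s  (SE {stats.se:.1f} s)")
```

prints

```
mean entry time 87.3 s  (SE 15.8 s, n=25, censored=0)
```

— the mean time for an unliganded receptor to first penetrate the
11.5 k_BT tetraspanin entry barrier, the quantity the barrier heights were
chosen to set (≈ 83 s). A reduced binding-rate sweep
(`examples/confinement_sweep.py`) prints

```
 k_bind  f_tet  f_cla  f_confined_all  f_confined_liganded  n_bound
 0.0010 0.0678 0.0235          0.0913                  NaN        0
 0.0056 0.0634 0.0237          0.0870               0.4719        1
 0.0316 0.0590 0.0357          0.0947               0.4656        6
 0.1778 0.0319 0.0739          0.1058               0.4705       14
 1.0000 0.0086 0.0889          0.0975               0.4684       17
```

showing the model's central result: as the ligand binding rate rises, the
tetraspanin-confined fraction falls and the clathrin-confined fraction
rises, while the overall confined fraction stays comparatively flat and the
*liganded* receptors are far more confined than the pool at large —
confinement changes mechanism, not amount. Each script in `examples/`
demonstrates one capability (single trajectories, first passage, the sweep,
ligand occupancy, detection/colocalization round trips).

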