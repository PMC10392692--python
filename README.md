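# asynsalt

Why does added salt *slow down* seeded α-synuclein amyloid formation, even
though the monomers and every catalytic surface involved are net negatively
charged at mildly acidic pH? Plain screening of a like-charge repulsion
should do the opposite. `asynsalt` is a research package for quantifying
this anomalous salt dependence from two directions:

* **Aggregation kinetics.** Seeded fibril growth with secondary nucleation
  is described by moment equations for fibril number P and mass M,

      dP/dt = k_n m^{n_c} + k_2 m^{n_2} M,   dM/dt = 2 k_+ m P,

  with m = m_tot − M and seeds entering through (M(0), P(0)). The package
  integrates these, evaluates an exact closed-form solution of the seeded
  family (k_n = 0), and globally fits normalized thioflavin-T (ThT) plate
  traces to recover the identifiable rate product k₂k₊ per salt
  concentration, with confidence intervals and censored half-times for
  fully inhibited conditions.

* **Electrostatics.** A constant-pH coarse-grained Monte Carlo model of one
  free 140-mer α-synuclein chain above a surface grafted with its own
  C-terminal tails (residues 101–140, one per 1,200 Å²) in a slit, with
  Debye–Hückel + Lennard-Jones interactions and titration swap moves. The
  simulation yields the mass-centre density g(z), the dipole-orientation
  profile ⟨μ·n̂/|μ|⟩(z) and charge-regulation summaries versus salt —
  showing a short-range attraction in which the positive N-terminal region
  buries into the negative tail layer, screened away at high ionic
  strength.

A sequence-level Henderson–Hasselbalch layer (net charge, isoelectric
point, region charges) and a synthetic-data generator with shipped ground
truth complete the pipeline. Audience: biophysicists analysing aggregation
kinetics or modelling IDP electrostatics who want a reproducible,
test-covered reference implementation at laptop scale.

## Worked example

Charge state of the packaged sequence:

```sh
$ asynsalt charge --ph 5.5
sequence        asyn_human      length  140
net_charge(pH=5.5)      -6.626 e
isoelectric_point       4.62
```

The protein is net negative at pH 5.5 (−6.6 e by intrinsic-pKa titration)
with an isoelectric point near 4.7 — yet salt *inhibits* its seeded
aggregation, which is the puzzle the rest of the package addresses.

Generate a synthetic seeded salt series (known ground truth), fit it, and
look at the recovered rate products:

```sh
$ asynsalt make-synthetic --preset salt-series --seed 1 --out data/
$ asynsalt fit --plate data/plate.tsv --meta data/meta.tsv --out fits.tsv
 salt_mM  t_half_h  censored  horizon_h  n_replicates
     0.0  1.360298     False       64.0             6
    20.0  1.894556     False       64.0             6
    40.0  2.675077     False       64.0             6
    80.0  5.326269     False       64.0             6
   120.0 10.679554     False       64.0             6
   200.0       NaN      True       64.0             6
   500.0       NaN      True       64.0             6
  1200.0       NaN      True       64.0             6
```

Half-times grow with salt; at and above 200 mM nothing aggregates within
the 64 h horizon and the rows are censored. `fits.tsv` holds the per-salt
k₂k₊ estimates with 95% confidence intervals; on the default synthetic
conditions (1% noise, three replicates) each is within a few percent of
the generator truth and the sequence decreases strictly with salt.

Run the desk-scale MC system (32 tails, same grafting density as the full
208-tail system) at 20 mM and analyse it:

```sh
$ asynsalt make-synthetic --preset mc-configs --seed 1 --out mc/
$ asynsalt cpmc-run --config mc/mc_desk.cfg --out traj/
$ asynsalt cpmc-analyze --traj traj/ --out profiles/
g(z) peak 8.79; alignment max 0.907
```

This takes ~10 minutes (two independent runs). At 20 mM the free chain is
strongly enriched at the tail layer (g(z) peak well above 1) and its dipole
points almost straight at the surface — a peak orientation of 0.85–0.9 at
this desk scale, varying a few percent between seed pairs — with the
positively charged N-terminal end buried in the grafted tails. Rerunning `mc_desk.cfg` with `c_salt_M = 0.5` collapses the peak
(near-surface g(z) < 1), scrambles the orientation, and makes both species
*more* negative (charge regulation): screening removes the short-range
attraction faster than it removes the long-range repulsion.

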