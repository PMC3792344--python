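# minratchet

Coarse-grained Monte-Carlo simulation of bacterial chromosome segregation by
entropic repulsion plus a membrane-tethering Brownian ratchet, with the
analysis metrics used on live-cell data.

## The problem

How *E. coli* — which lacks a dedicated mitotic machinery — partitions its
sister chromosomes is a long-standing question. Entropic repulsion between
the two confined, self-avoiding chromosomes pushes them apart initially, but
weakens as their overlap shrinks and cannot finish the job. A polar gradient
of transient DNA-tethering sites on the inner membrane (as produced by the
pole-to-pole MinD oscillation) can rectify the chromosomes' random motion
into poleward drift: segments that wander poleward are briefly held, backward
motion is suppressed, and the chromosome ratchets toward its pole.

`minratchet` is the simulator and analysis toolkit for this mechanism,
aimed at anyone studying polymer models of nucleoid organisation or
intracellular gradients.

## The model

Each sister chromosome is a ring of N = 80 monomers on a cubic lattice,
evolved with the bond-fluctuation method (BFM): a monomer occupies the 8
sites of a unit cube, bonds are restricted to the 108-vector set with squared
lengths {4, 5, 6, 9, 10} (chains can never cross), and one Monte-Carlo step
(MCS) is one attempted single-site displacement per monomer. The two rings
live in a hard-walled 80 × 10 × 10 box (aspect ratio 1:8, the shape of an
*E. coli* cell) and start intermixed at mid-cell.

Tethering temporarily immobilizes monomers near the lateral wall with
probability p(x, t) per MCS; dwell times are geometric with mean τ. The
spatial regimes are: none, uniform, a static polar gradient
p(x) = p_max·(2|x/Lx − ½|)^s, an oscillating gradient (one active pole,
alternating every half-cycle T), and a gradient driven by a (synthetic or
measured) MinD axial fluorescence profile series. Defaults put the model in
the weak-and-transient ratchet regime: p_max = 0.01 per MCS, τ = 100 MCS,
border distance 2, T = 5000 MCS (see `docs/methods.md`).

Observables: relative axial centre of mass cm_rel ∈ [−½, ½] per ring,
axial density profiles, radius of gyration, cross-run CM distributions with
the separation statistic Δ = mean |cm_rel|, and a force–distance probe
(equilibrium CM separation under an applied attractive potential U = f·d).

The `profile_metrics` module implements the in-vivo quantifications on 1D
inputs: nucleoid separation depth R = 1 − I_valley/mean(I_peaks) and lobe
distance D from axial intensity profiles, and the apparent diffusion
coefficient D_app = MSD-slope/4 from 2D focus tracks.

## Worked example

```python
import numpy as np
from minratchet import ExperimentSpec, run_ensemble

deltas = {}
for condition in ("no_tether", "static_gradient"):
    spec = ExperimentSpec(condition=condition, n_replicates=8,
                          n_mcs=500_000, seed_base=42)
    summary, runs = run_ensemble(spec)
    deltas[condition] = summary.delta
    print(f"{condition:16s} delta = {summary.delta:.3f} "
          f"(sd over polymers {summary.delta_sd:.3f})")
```

prints (about one minute of compute):

```
no_tether        delta = 0.240 (sd over polymers 0.028)
static_gradient  delta = 0.262 (sd over polymers 0.039)
```

Without tethering, entropic repulsion alone stalls near |cm_rel| ≈ 0.24;
with the static polar gradient the rings ratchet further toward the quarter
positions (the centres of the two cell halves — at larger ensembles the
gradient Δ settles near 0.27–0.30). The same workflow runs the
oscillating, MinD-profile-driven, uniform, 10×-dwell and entropy-off
controls; `minratchet --help` lists the equivalent CLI commands.

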