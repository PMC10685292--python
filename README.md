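# superplan

Superiorized feasibility-seeking for linearly constrained inverse
radiotherapy treatment planning (IMRT fluence-map optimization).

## The problem

Inverse planning discretizes the patient into $n$ voxels and the radiation
field into $m$ beamlets with nonnegative intensities
$x \in \mathbb{R}^m_{\ge 0}$.  A precomputed sparse **dose influence matrix**
$A \in \mathbb{R}^{n \times m}_{\ge 0}$ maps intensities to voxel doses,
$d = Ax$.  The clinical prescription becomes per-voxel dose slabs

$$\ell_q \le \langle a_i, x\rangle \le u_q \quad \text{for all } i \in S_q,
\qquad x \ge 0,$$

where $S_q$ are the segmented volumes of interest (a C-shaped target wants
$59\,\mathrm{Gy} < d < 61\,\mathrm{Gy}$, organs at risk carry pure upper
bounds), plus a weighted-sum objective
$f(x) = \sum_p w_p f_p(d(x))$ built from standard penalty functions
(squared deviation, one-sided overdose/underdose, mean dose, DVH penalties).

`superplan` solves this two ways:

1. **Bare feasibility-seeking** — the sequential AMS relaxation method.
   Each sweep visits every actively constrained voxel in a control-sequence
   order and projects onto the violated half-space of its slab,
   $x' = x - \lambda\nu_i \frac{(\langle a_i,x\rangle - u_i)_+}{\|a_i\|_2^2} a_i$
   (and symmetrically for the lower side), with relaxation
   $\lambda \in (0,2]$ and per-voxel weights $\nu_i \in (0,1]$, followed by
   one projection onto the nonnegative orthant.
2. **Superiorization** — the same basic algorithm, perturbed.  Between
   sweeps, up to $N$ objective-reduction steps $x \gets x + \beta v$ are
   taken along the normalized negative gradient $v$, with step sizes
   $\beta = \alpha^s$, $\alpha \in (0,1)$, where the exponent $s$ only ever
   grows (so $\sum \beta$ is finite and the feasibility-seeking behavior is
   preserved).  Projection weights may decay as $\eta^k$ per sweep.  The run
   stops when both the objective $f$ and the proximity
   $V(x) = \frac{1}{n_\text{act}}\sum_i
   \frac{(\ell_i - \langle a_i,x\rangle)_+^2 + (\langle a_i,x\rangle - u_i)_+^2}
   {\|a_i\|_2^2}$
   stagnate in relative terms for several consecutive iterations.

The superiorized run ends at a *feasible* point with a *reduced — not
necessarily minimal —* objective value: a satisficing alternative to full
constrained optimization that needs only gradients and cheap projections.

Everything is testable without clinical data: the package generates a
TG119-style horseshoe phantom (C-shaped target, central core organ-at-risk,
elliptical body) with an analytic multi-field beamlet dose model, and random
toy feasibility problems with known witnesses or provable infeasibility.

## Worked example

`examples/03_superiorized_planning.py` runs both modes on the packaged
phantom benchmark (4096 voxels, 144 beamlets, feasible by construction):

```
phantom: 4096 voxels, 144 beamlets, 1796 active dose slabs
objective at start              f(x0) =      3.6e+06
objective after iteration 1     f     =    5.003e+05
objective at end (superiorized) f     =         7575
objective of bare-AMS solution  f     =     4.25e+04
final max violation: bare 5.88e-04 Gy, superiorized 0.00e+00 Gy
both solutions satisfy the dose slabs; superiorization additionally steered
the iterates to a lower objective value.
```

Reading: starting from zero fluence the objective is huge (no dose in the
target).  One superiorized iteration already removes 86% of it — the
typical strong initial decrease.  Both modes end feasible (max slab
violation well under the 0.01 Gy acceptability threshold), but the
superiorized fluence ends at roughly one fifth of the objective value that
bare feasibility-seeking happens to land on.

The other examples build the phantom and dose model (`01`), run bare
feasibility-seeking on a toy system (`02`), and evaluate a plan through
DVHs and dose statistics (`04`).  A thin CLI wraps the same runners:

```sh
superplan phantom --out ph/
superplan plan --config my_plan.yaml
superplan evaluate --result plan_output/
superplan compare run_a/ run_b/ --out report.csv
```

## Layout

- `src/superplan/phantom.py` — grids, structures, dose model, toy problems
- `src/superplan/objectives.py` — dose objectives, gradients, DVH quantile
- `src/superplan/feasibility.py` — hyperslab constraints, AMS sweep, proximity
- `src/superplan/superiorize.py` — perturbation phase, superiorized loop
- `src/superplan/evaluation.py` — DVHs, dose statistics, run comparison
- `src/superplan/{config,run,cli,io}.py` — config schema, runners, CLI, disk format
- `docs/methods.md` — models, conventions, numerical choices, limitations
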