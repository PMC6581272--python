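# ribofrag

Population dynamics of **fragmented ribozyme replicases** in dividing
protocells with horizontal transfer.

## The problem

A plausible route to a self-replicating RNA polymerase is to split the
ribozyme into short fragments — short enough to be copied by the ribozyme
itself — that self-assemble into the functional catalyst.  With two
fragments X and Y and catalyst C the reaction network is

    X + Y  --k_f-->  C          C --k_b--> X + Y
    X + C  --k_x-->  2X + C     Y + C --k_y--> 2Y + C

Continued self-replication requires *balanced* production of both
fragments, but the cycle carries a positive feedback: writing
x_tot = x + c and y_tot = y + c, the well-mixed dynamics give

    d/dt (x_tot / y_tot) = k c² / y_tot² · (x_tot − y_tot),

so any excess of one fragment amplifies itself, the minor fragment is
diluted out, and replication stops.  This package implements, end to end,
the two mechanisms that rescue the system:

1. **Compartmentalization** — N_cell protocells, each running the
   reactions stochastically (exact Gillespie simulation over all cells'
   channels).  A cell whose fragment count V = n_x + n_y + 2 n_c reaches
   the threshold V_div divides, molecules partitioned binomially between
   daughters; a randomly chosen cell is removed to keep N_cell fixed.
   Selection against badly composed cells (the stochastic corrector)
   works, but only for narrow V_div and large enough N_cell.
2. **Horizontal transfer** — every molecule leaves its cell at rate D and
   lands in a random other cell.  X-dominant and Y-dominant cells then
   feed each other's minority fragment, and a *negative
   frequency-dependent selection* keeps the two cell types at 1:1.

The analytical core is a reduced model of two coupled subsystems (the
X- and Y-dominant halves of the population) with total-X concentrations
x_i, drift F(x) = −x²(1−x)²(1−2x)/4 and coupling D/2·(x_j − x_i).  Its
asymmetric fixed point x₁ = ½(1+√(1−4√(2D))), x₂ = 1−x₁ has eigenvalues
λ₁ = 5D − √(2D)/2 along (1,1) and λ₂ = λ₁ − D along (1,−1), giving the
two bifurcations that bound the stable-transfer window:

* **D\* = 0.02** — above it the X/Y symmetry breaks (λ₁ > 0);
* **D⁺ = 1/32 = 0.03125** — the asymmetric pair merges with the
  symmetric point (λ₂ → 0).

Stable balanced replication therefore requires 0 < D < D\*.

## Worked example

Fixed points and bifurcations of the reduced model:

```bash
$ ribofrag reduced --d 0.01 --out reduced.json
D*=0.02000000 D+=0.03125000 (5 fixed points) -> reduced.json
```

At D = 0.01 the stable fixed point is (x₁, x₂) = (0.8295127, 0.1704873)
with eigenvalues (−0.0207107, −0.0307107): each subsystem holds ~83% of
one fragment and ~17% of the other, and the state is attracting.  The
frequency-dependent selection behind the 1:1 population balance:

```python
>>> from ribofrag import volume_perturbation
>>> r = volume_perturbation(D=0.01, eps=0.01)   # subsystem 1 volume 51%
delta1=0.0031821 delta2=0.0031821               # both x_tot rise equally
mu1=0.0599581 mu*=0.0607107 mu2=0.0614622       # minority grows faster
gamma=0.0752                                    # selection strength > 0
```

The oversized (majority) subsystem becomes more internally asymmetric and
grows slower; the minority subsystem grows faster by the same margin —
the volume split relaxes back to 1/2 : 1/2.

Population simulation (Gillespie, 100 cells, division threshold 1000):

```bash
$ ribofrag simulate --seed 4 --max-divisions 2000 --out divisions.csv
status=max_divisions divisions=2000 events=5343387 -> divisions.csv
```

The division records (t, cell, X_tot, Y_tot, n_c) show the cells
differentiating into X-dominant and Y-dominant types that coexist in
roughly equal numbers for D = 0.01 — and fixing to a single type, then
collapsing, for D = 0.

Other subcommands: `ribofrag batch` (deterministic trajectories),
`ribofrag phase-diagram` (stability over a (V_div, N_cell) grid),
`ribofrag minor-fraction` (minor-fragment content of dividing cells vs
the analytic fixed point).

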