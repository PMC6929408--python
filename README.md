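# lscdock

FFT-accelerated rigid-body protein–protein docking with a **long-range
shape-complementarity** score.

Predicting how two proteins associate from their individual structures is
a standard task in structural biology; grid-based FFT docking is the
classic global approach.  `lscdock` implements the long-range variant of
pairwise shape complementarity: receptor and ligand are discretized onto a
cubic lattice (1.2 Å spacing), the inside of each protein is layered into
**surface / near-surface / core**, and every grid point gets a complex
value

```
receptor R(l,m,n):  surface   −Σ exp[−(r−1)²] + J     (Σ over the ±3 index box)
                    near-surf −1 + 2J·Σ exp(−r²)      (Σ over the ±1 index box)
                    core      −1 + 10J
ligand   L(l,m,n):  surface    1 − J
                    near-surf  1 − 2J·Σ exp(−r²)
                    core       1 − 10J
```

with both sums over near-surface/core points and r in lattice units — the
exponential ±3 reach is what lets atoms several layers away still count.
For each ligand orientation the correlation

```
E(o,p,q) = Re[ Σ_{l,m,n} R(l,m,n) · L(l+o, m+p, n+q) ]      (indices mod N)
```

is evaluated for **all** translations at once by 3D FFT.  Orientations are
sampled on a deterministic quasi-uniform Euler grid — 4392 orientations at
the default 15° interval — and the best translation per orientation is
retained, giving 4392 ranked candidate poses per run.  Pose quality is
measured as ligand-Cα RMSD after receptor backbone superposition; a pose
under 10 Å is a *hit*, and benchmarks report success rate and mean hits
among the top-K predictions.  See `docs/methods.md` for the model details,
including why the default `repulsive_core` ranking scores the printed
correlation as an energy.

## Worked example

No downloads needed — the package generates its own test complexes
(knob/socket pseudo-proteins with a known bound pose):

```bash
lscdock fixtures --n-cases 1 --seed 1 -o bench
lscdock dock bench/case001_receptor.pdb bench/case001_ligand.pdb \
        -o preds/case001 --interval 15 --top-poses 1
lscdock eval bench/cases.tsv preds --k-values 1,10,100,1000 -o summary.tsv
```

which prints

```
1 cases -> bench/cases.tsv
4392 predictions -> preds/case001_predictions.tsv
case001	first_hit_rank=1
summary for 1 cases -> summary.tsv
```

`preds/case001_predictions.tsv` holds all 4392 poses, ranked by score,
with the run parameters echoed in the header:

```
rank  rotation_index  alpha       beta        gamma   tx    ty   tz    score
0     4022            283.796596  146.633006  210.0   7.2   0.0  -1.2  660.614729
1     2039            30.652180   85.588274   345.0   7.2   0.0   0.0  655.951213
```

Each row is one ligand orientation (z-y-z Euler angles, degrees) with its
best translation (Å, receptor frame) and shape-complementarity score
(higher = better fit).  `first_hit_rank=1` means the top-ranked pose
already sits within 10 Å ligand RMSD of the true bound pose — redocking
recovered the socket.  The summary mirrors benchmark-style reporting:

```
group  metric        top1    top10   top100  top1000
all    success_rate  100.00  100.00  100.00  100.00
all    mean_hits     1.00    10.00   100.00  1000.00
```

The sign-mode audit (`lscdock audit`) redocks the fixture under both score
conventions and reports which one behaves physically:

```
repulsive_core: PASS (contact=20, core_clash=0/158 ligand core cells, top score 678.91)
as_printed:     FAIL (contact=18, core_clash=146/165 ligand core cells, top score 26887.50)
```

Real proteins work the same way: `lscdock dock receptor.pdb ligand.pdb`
(HETATM excluded, first MODEL, highest-occupancy altlocs; radii from a
substitutable element table).

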