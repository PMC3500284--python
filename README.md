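# ssefold

De novo prediction of protein topology by assembling idealized secondary
structure elements (SSEs).

Most de novo structure prediction methods fold a continuous chain, which
makes non-local contacts — the defining feature of complex topologies —
expensive to sample. `ssefold` takes the opposite route: it treats
α-helices and β-strands as rigid idealized bodies, leaves flexible loops
out of the search entirely, and assembles the SSE arrangement directly with
a Monte Carlo Metropolis simulated-annealing search. Chain breaks are only
required to be *closable by a loop*; once a topology is found, missing loop
residues are grown with Ramachandran-biased dihedrals and closed by cyclic
coordinate descent (CCD). The package is aimed at structural
bioinformaticians studying topology sampling, and at settings where sparse
experimental data restrains SSE positions.

## Method at a glance

* **Pool**: per-residue 3-state predictions (PSIPRED `.ss2` plus a generic
  TSV dialect) are thresholded at *p* ≥ 0.5, filtered to ≥ 5 residues per
  helix and ≥ 3 per strand, and refined by a 1000-step Monte Carlo
  minimization of the agreement score Σᵢ −log *p*ᵢ(assigned state).
* **Search**: models are altered by a registry of moves in six categories
  (add, remove, swap, single-SSE, SSE-pair, domain). A proposal with energy
  *E*new against the best energy *E*best so far is `improved` if
  *E*new < *E*best, otherwise `accepted` with probability
  exp(−(*E*new−*E*best)/kT) or `rejected` (resuming from the best model);
  moves whose prerequisites are absent are `skipped`. The temperature
  starts at 500 and is adjusted every 10th step to track an acceptance
  target falling linearly 0.5 → 0.2. Assembly runs ≤ 5000 steps (stop after
  1000 consecutive non-improving), refinement ≤ 2000 (stop after 400).
* **Energy**: a weighted sum of 12 terms — amino acid clash, pair distance,
  solvation, SSE clash, SSE packing, strand pairing, loop length, loop
  closure (a chain break wider than 2.56·(*n*+1)+2.0 Å over *n* loop
  residues is heavily penalized), radius of gyration, two secondary
  structure agreement terms, and contact order. Solvation and agreement
  also score the unfolded part of the protein.
* **Loops**: SSEs are trimmed by one residue per side, loops grown
  best-of-K from Ramachandran tables, and closed by CCD (closed-form
  per-dihedral minimization of the 3-atom anchor RMSD, tolerance 0.08 Å),
  with force-close rounds for stubborn breaks.
* **Metrics**: Kabsch RMSD; RMSD100 = RMSD / (1 + ln √(n/100)); contact
  order CO (mean sequence separation of Cβ pairs within 8 Å), RCO = CO/L,
  NCO = CO²/L; contact recovery CR (percent of native contacts with
  sequence separation ≥ 12 and Cβ distance < 8 Å present in a model);
  native-like = RMSD100 < 8.0 Å or CR > 20%; and a non-symmetric
  move-correlation statistic over search trajectories.

## Worked example

Everything below runs on a synthetic, designed three-helix bundle — no
downloads needed:

```
$ ssefold toyset --seed 3 --out-dir fixture
fixture bundle written to fixture

$ ssefold pool --ss2 fixture/perfect.ss2 --pred-tsv fixture/perfect.pred.tsv \
    --out fixture/pred.pool --native fixture/native.assignment --seed 1
Q3 100.0  %found 100.0  shift 0.00

$ ssefold fold --fasta fixture/sequence.fasta --pool fixture/pred.pool \
    --ss2 fixture/perfect.ss2 --pred-tsv fixture/perfect.pred.tsv \
    --n-models 5 --seed 7 --out-dir models
model_000.pdb   E=-26.55
model_001.pdb   E=-14.09
model_002.pdb   E=-13.22
model_003.pdb   E=-12.90
model_004.pdb   E=6.36

$ ssefold loops --pdb models/model_000.pdb --pool fixture/pred.pool \
    --seed 2 --out models/model_000_complete.pdb
bridge 17-23 closed=True distance=0.079
bridge 38-44 closed=True distance=0.079
tail_n 1-2 closed=True distance=0.000
tail_c 59-59 closed=True distance=0.000

$ ssefold analyze --model models/model_000.pdb \
    --model models/model_000_complete.pdb \
    --native fixture/native_sse.pdb --out metrics.tsv
models/model_000.pdb            RMSD100 3.81    CR 46.6
models/model_000_complete.pdb   RMSD100 3.99    CR 46.6
```

Reading the output: the pool built from the perfect predictions recovers
every native SSE with no boundary shift; the best-energy of five models
(−26.55 score units) reproduces the native bundle to 3.81 Å RMSD100
(well inside the 8.0 Å native-like cutoff) and recovers 46.6% of native
long-range contacts; loop building closes both inter-helix chain breaks to
within the 0.08 Å anchor tolerance, and the completed model stays at
essentially the same accuracy.

Pool files are plain text (`HELIX first last` / `STRAND first last`,
1-based inclusive); trajectories, metrics and energy breakdowns are TSV;
configuration is YAML (`RunConfig.to_yaml` writes a complete template).

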