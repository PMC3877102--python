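# Methods

## The screening model

A docking study for one (compound, protein) pair starts from pose sets
produced by up to three docking tools (labelled eHiTS, GOLD and VINA by
convention; adapters may define others). The pipeline assumes poses are
geometrically plausible — pose *generation* is the one thing docking
engines do well — and replaces only their scoring:

1. every pose is featurized and re-scored by system A;
2. each tool's top re-scored candidate is retained;
3. system B assigns each retained candidate a probability of being the
   most predictive mode and the arg-max candidate's re-score is reported
   as the final docking score, directly on the pKd/pKi scale
   (pKd = −log₁₀ Kd in molar; roughly 0–12 from weak to strong binding).

### Features

**Contacts (36).** For the nine ligand elements C,N,O,F,P,S,Cl,Br,I
crossed with the four protein elements C,N,O,S, the number of
(ligand atom, protein atom) pairs within 12 Å is counted. The full 9×9
enumeration gives 81 ordered pairs; the 45 with a halogen or phosphorus
on the protein side are omitted because protein polymers contain none,
leaving 36. The distance test is inclusive (d ≤ 12 Å): atoms exactly at
the cutoff are a measure-zero set and inclusivity matches the "within"
reading. Hydrogens never count (the element list excludes H, and
benchmark protein structures are mostly hydrogen-free); waters, metal
ions and other hetero records are excluded from the protein side via an
explicit flag-based filter, never silently. The counter is vectorized
(per-element-pair distance matrices) and is required by test to be
bit-identical to a plain double-loop enumeration.

**Descriptors (74).** Compound-level physicochemical properties in six
groups: constitutional (12), topological (6), connectivity/shape (12),
electronic/charge (18), lipophilicity/solubility (12), drug-likeness/
surface (14). The classical commercial descriptor sets these groups echo
are not reproducible in the open; the concrete schema here is our own
construction on RDKit and is frozen — the exact (name, group) listing
ships as `dockscreen/data/descriptor_schema.json` and the learning
systems refuse feature vectors whose schema hash differs. A descriptor
that fails or returns a non-finite value is imputed (training-set median
when available, else 0) and logged; models never see NaN. Descriptors are
computed on input connectivity, not on docked conformers: they are
compound properties, constant across poses.

### System A (re-scoring)

Random-Forest regression on the 110-feature vector. Defaults follow the
classic regression-forest convention: 500 trees, p/3 ≈ 36 candidate
features per split, fully grown trees, all overridable. Predictions are
means over tree leaves, hence bounded by the training label range.
Training tables mix pKd and pKi on one scale, as affinity-benchmark
practice does. Inactive augmentation: confirmed non-binders are appended
with label exactly 1.0 (pKd) and `active=False`; the default augmentation
size is capped at the number of actives so dummies cannot drown the
signal. Training requires ≥ 20 examples and ≥ 2 distinct labels.

### System B (mode selection)

Multinomial logistic regression fitted by maximum likelihood (lbfgs,
tolerance 1e-8). Its feature vector concatenates the candidates' contact
vectors in fixed tool-slot order (zero-filled for absent tools), the
availability mask, and the shared 74 descriptors — a joint encoding,
chosen because selecting *among* modes is a comparison the model cannot
make if it sees candidates one at a time. Candidate re-scores are
deliberately excluded as features to keep the selector independent of the
quantity it is judged against. Numerical choices: features are
standardized internally (the scaler travels with the model); a tiny
per-observation ridge (1e-6) keeps the optimum finite on separable data
and makes the fit invariant under row duplication. At prediction,
probabilities are renormalized over the tools actually present; exact
ties resolve by the fixed priority eHiTS > GOLD > VINA.

Training labels come from `label_best_mode`: the candidate whose re-score
minimizes |score − experimental pKd|, same tie rule.

### Validation protocol

`run_validation` repeats, 25 times by default with seeds 1..25: randomly
hold out 15% of the labelled complexes, train system A from scratch on
the remaining 85%, predict the held-out set, record the Pearson
correlation with experimental affinity; then report per-iteration R,
mean and s.d. Operating on a flat feature table, the protocol validates
system A alone (mode selection needs labelled pose triples, which a
table does not carry) and records that in the report's `systems` field.
Both systems are re-trained inside every partition when triples are
available, so nothing leaks across the split.

## Selectivity and network projection

Selectivity score S = |{proteins with score > cutoff}| / |proteins
tested|, strict inequality, default cutoff 5.52 pKd (−log₁₀ of 3 µM,
stored at the 2-decimal precision it is conventionally quoted at;
overridable), tolerance cutoff 4.52. Target calling partitions every
scored protein into exactly one of hit / tolerance-only (score in
(4.52, 5.52]) / non-hit, split against a user-supplied primary-target
list.

Scores project onto an SBML Level 2 model as a white-to-red scale:
linear interpolation from (255,255,255) at 0 to (255,0,0) at 10,
channels rounded half-up, scores outside [0,10] clamped. The concrete
RGB endpoints and rounding are this package's choices; only
"white-to-red over 0–10, clamp above" is inherited convention. Species
with no score — structure unavailable, or no tool produced a mode —
render gray (190,190,190). Score-to-species joining is by SBML species
id with a logged case-insensitive display-name fallback; unmatched scores
are returned as orphans, never dropped. Identity-to-structure resolution
(e.g. UniProt/PDB lookups) is externalized to a user-supplied mapping
rather than live web queries, so tests and screening runs are fully
offline.

## Synthetic fixtures: what they emulate, what they don't

The generators provide ground-truth-bearing stand-ins for licensed
benchmark data (affinity-annotated co-crystal sets, kinase panels):

- **Toy complexes** are element-labelled point clouds placed uniformly in
  a 16 Å box (40 protein atoms from {C,N,O,S}, 12 ligand atoms from the
  nine-element set plus H), sized so both populated and empty contact
  types occur. They are not chemically valid polymers; they exist to make
  contact counts exactly countable by an independent double loop.
- **Training sets** draw contact counts as Poisson(8) and take descriptors
  from a bundled 50-molecule drug-like SMILES list, cycled
  deterministically. The label is a fixed linear function of five contact
  features plus one interaction term (intercept 6.5, giving a realistic
  2–11 pKd spread), Gaussian noise σ (default 0), clipped to [1, 12];
  a `fraction_inactive` subset is relabelled to pKd = 1.
- **Pose triples** make the best tool a deterministic threshold rule on a
  designated contact feature and additionally enrich two signature
  contact types of the winning candidate; simulated re-scores place the
  winner's score nearest the experimental value, so the stored label,
  the rule and `label_best_mode` all agree by construction.
- **Pathway fixture**: a 14-protein, 27-reaction EGFR-style SBML Level 2
  model with canonical-looking wiring (EGF→EGFR→adaptors→Ras/Raf→MEK/ERK
  →nuclear factors).

Everything is byte-reproducible given (recipe, seed), and the on-disk
writers emit real PDB/SDF/JSON/SBML so fixtures exercise the actual
parsers. Because the feature→affinity map is smooth and the features are
sampled independently, passing the recovery tests shows the learning
machinery is implemented correctly — it does not show that real docking
features carry this much signal, and published benchmark correlations
(built on licensed structure sets and commercial docking engines) are
not reproduced here.

## Problem sizes and numerical conventions

The recovery experiments run at n = 2000 examples for the 25-iteration
validation protocol and 1500 triples for the selector, sizes at which the
sampling noise of the synthetic conditions is well below the asserted
margins. Model files serialize with joblib and carry a feature-schema
hash; loading under a different schema fails loudly. All randomness flows
through explicit integer seeds (`numpy.random.default_rng`); forests and
logits are single-threaded for determinism. Degenerate inputs fail with
typed errors (`FormatError`, `NeedsEmbeddingError`, `SchemaMismatchError`,
`DegenerateLabelsError`, `UndefinedCorrelationError`) rather than
propagating NaN.

## Known limitations

- No docking engines are executed; per-tool pose-count conventions
  (eHiTS 1000, GOLD 300, VINA bounded by a 10 kcal/mol energy window) are
  carried as adapter metadata only.
- 2D→3D embedding is out of scope: SMILES input is accepted but refused
  with a typed error wherever 3D coordinates are required.
- The 74-descriptor schema is an open surrogate; numerical agreement with
  any proprietary descriptor package is a non-goal.
- Metal ions are excluded from contact counting (outside {C,N,O,S}).
- SBML support covers species-list reading and sidecar annotation output;
  rendering inside pathway editors is out of scope.
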