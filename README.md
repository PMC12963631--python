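# scforge

Charge-driven reformatting of antibodies as soluble cytoplasmic scFv
intrabodies, as a tested library + CLI:

- **seqio** — FASTA / table I/O and decomposition of assembled scFv
  sequences back into tag / domain / linker parts.
- **numbering** — Chothia numbering by alignment to embedded numbered
  templates (VH, VL-kappa, VL-lambda), CDR/framework segmentation,
  conserved salt-bridge checks (VL 61–82, VH 66–86), position-addressed
  mutations, Fv extraction from full-length chains.
- **physchem** — counting net charge `(K+R)−(D+E)`, charge at pH 5.5
  `(K+R+H)−(D+E)`, isoelectric point (Henderson–Hasselbalch bisection
  averaged over two pKa tables), GRAVY, aliphatic index (mole percent of
  A/V/I/L), per-region charge sums.
- **solubility** — the linear charge→percent-solubility predictor
  (`percent = −4.6237 × charge + 8.2469`, clamped to [0, 100]), the
  strict >70% high-solubility classifier, and OLS fitting of
  charge/solubility data.
- **construct** — linker library ((G₄S)₄ … (GE)₁₀, charges 0…−10), tag
  library (3xFLAG, HA, myc), domain-orientation rule (auto ⇒ VLVH),
  charge budgeting toward a target solubility.
- **redesign** — fixed-position masks (`cdr_only`, `extended`,
  `production`), validation of inverse-folding outputs (fixed positions,
  cysteines, salt bridges), solubility+rank sorting, ensemble
  conservation/consensus statistics.
- **cohort** — repertoire filtering, CDR-redundancy deduplication
  (lowest-charge representative), linker surveys, property histograms.
- **synthetic** — deterministic generators: variable-domain pairs with
  controllable charge composition, mask-respecting design ensembles,
  noisy linear charge→solubility datasets.

## CLI

```bash
forge profile fv.fasta                       # physicochemical table
forge number fv.fasta                        # Chothia labels + regions
forge predict scfv.fasta --mode asis         # percent solubility
forge assemble fv.fasta --linker G4D4 --tags 3xFLAG,HA
forge parse scfv.fasta                       # tag/domain/linker breakdown
forge rank parent.fasta candidates.fasta --mode production \
    --mask-json mask.json --out-fasta ranked.fasta
forge fit data.tsv                           # OLS of percent on charge
forge simulate fv|ensemble|dataset ...       # synthetic fixtures
```

Coordinates in all reports: sequence indices are 0-based half-open,
Chothia labels 1-based.

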