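# gh51kit

Characterization pipeline for GH51 α-L-arabinofuranosidase protein
families: degenerate-motif validation, catalytic acid/base
classification, motif-anchored excision of the N-terminal CBM4-like
domain, native profile-HMM construction and scanning, per-group domain
prevalence statistics, Gblocks-style alignment block trimming,
neighbor-joining phylogeny with bootstrap support, and global pairwise
percent identity.

## Modules

| module | role |
| --- | --- |
| `gh51kit.io` | FASTA / aligned-FASTA / Stockholm I/O, `Msa` with column↔residue coordinate maps, group tables |
| `gh51kit.motifs` | degenerate motif compilation and scanning (`G-N-E/Q`, `S-E-Y-x-V`, ...), family validation (length ≥ 350 + both catalytic motifs), acid/base classification (G-N-E / G-N-Q / G-N-D / G-S-N) |
| `gh51kit.domains` | excision of the domain region between the conserved `L-x-V-D` and `S-x-x-P` anchors |
| `gh51kit.hmm` | profile HMM build (match/insert/delete, pseudocounts, uniform row weights), Forward/Viterbi log-odds scoring in bits, local and glocal modes, plain-text serialization, collection scanning with the >200-residue rule |
| `gh51kit.prevalence` | per-group hit percentages (half-up, one decimal) with Wilson 95% intervals |
| `gh51kit.trim` | column classification (gap-half rule, strict majority / 0.85 conservation) and block trimming (max 15 contiguous nonconserved, min block 2) |
| `gh51kit.phylo` | p-distances, neighbor joining, column-resampling bootstrap, outgroup rooting, clade vs. catalytic-status congruence |
| `gh51kit.align` | global affine-gap alignment (BLOSUM62, open 10 / extend 0.5) and percent identity |
| `gh51kit.simulate` | synthetic labeled families with planted domains, catalytic variants, indel history, true alignment, and decoys |
| `gh51kit.cli` | `gh51kit` command-line interface and end-to-end pipeline |

Neighbor joining with p-distances is a deliberate, documented stand-in
for maximum-likelihood tree inference; the native profile HMM is a
stand-in for hmmbuild/hmmscan (HMMER is used only as an optional test
oracle for rank agreement, never as the implementation).

## Tests

```sh
python -m pytest -q tests/
```

The suite contains per-module unit tests, property tests (scanning vs. a
brute-force window oracle, Forward/Viterbi vs. exhaustive path
enumeration, NJ vs. random additive matrices, alignment vs. exhaustive
enumeration) and `tests/test_acceptance.py` with the acceptance
criteria.  One prevalence-arithmetic case (61.8 from 1354/2189) is
knowingly red: that printed value is a truncation (the exact value is
61.8547%, i.e. 61.9 at one decimal half-up) and is inconsistent with the
other printed values; see `percent`'s documented convention.

## CLI

```sh
gh51kit simulate -o sim --seed 1 --n 24 --domain-prevalence 0.8 --q-fraction 0.4
gh51kit validate sim/family.fasta -o validation.tsv
gh51kit classify sim/family.fasta -o catalytic.tsv
gh51kit excise sim/family.afa -o excised.afa --segments segments.tsv
gh51kit hmmbuild excised.afa -o profile.txt
gh51kit hmmscan profile.txt sim/family.fasta -o scan.tsv
gh51kit prevalence scan.tsv sim/groups.tsv -o prevalence.tsv
gh51kit trim sim/family.afa -o trimmed.afa
gh51kit tree trimmed.afa -o tree.nwk --bootstrap 100 --seed 1
gh51kit run config.yaml          # full pipeline from a YAML config
```

Minimal `config.yaml`:

```yaml
sequences: sim/family.fasta
alignment: sim/family.afa
groups: sim/groups.tsv
outdir: out
seed: 1
bootstrap_reps: 100
```

Exit codes: 0 success, 2 configuration error, 3 data error.  Reruns with
identical config and inputs are byte-identical.

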