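# ystrkit

Analysis toolkit for Y-chromosomal STR haplotype data: haplotype-level
forensic parameters, per-locus statistics and allele-anomaly QC, pairwise
population distances (haploid AMOVA RST, Nei standard distance), classical
MDS ordination, UPGMA dendrograms with Newick export, median-joining
haplotype networks, and a founder-expansion stepwise-mutation simulator so
every stage can be exercised on synthetic data.

## Modules

| Module | What it does |
| --- | --- |
| `ystrkit.panels` | Marker panels (built-ins `yfiler_plus_27`, `single_copy_23`, `yfiler_17`), the tab-delimited haplotype table dialect, allele canonicalization (dual-copy pairs, microvariants, duplications, nulls) and anomaly flagging |
| `ystrkit.forensic` | Multiplicity spectrum; HD, HMP, DC, unique-haplotype fraction; per-locus allele frequencies, GD, PIC, PM, PD, PE, TPI; dual-copy pair statistics; categorical diversity |
| `ystrkit.distances` | Pairwise RST (one-level haploid AMOVA on repeat scores) and Nei (1972) standard distance; classical (Torgerson) MDS; UPGMA dendrogram / Newick |
| `ystrkit.network` | Median-joining networks (epsilon-relaxed minimum spanning network, triplet medians, obsolete-median pruning, maximum-parsimony post-processing), TSV/GML export |
| `ystrkit.simulate` | Founder-expansion stepwise-mutation simulator with subpopulation divergence and controllable anomaly injection; spectrum-shaped fixture builder |
| `ystrkit.cli` | `ystr` command-line front end |

## CLI

```sh
ystr simulate --pops 3 --size 50 --generations 40 --divergence 100 --seed 7 -o out
ystr stats out/haplotypes.tsv --by population -o out
ystr locus-stats out/haplotypes.tsv -o out
ystr dist out/haplotypes.tsv --method rst -o out
ystr mds out/dist_rst.tsv -k 2 -o out
ystr tree out/dist_rst.tsv -o out
ystr network out/haplotypes.tsv --epsilon 0 -o out
```

All outputs are plain TSV/JSON/Newick; each subcommand writes a
machine-readable run log (`<command>_run.json`) with parameters and
exclusion decisions, and runs are deterministic for a fixed seed.

## Table dialect

UTF-8, tab-delimited, header row with `sample_id`, `population`, optional
`region`/`haplogroup`, and one column per marker. Dual-copy markers are
hyphen-joined (`11-14`, order-free), duplications at single-copy markers
comma-joined (`15,16`), nulls `-`, microvariants decimal (`17.2`).
Out-of-range alleles warn by default and fail under `--strict`.

## Conventions

- Haplotype identity uses the full canonicalized allele string, including
  microvariants, duplications and nulls.
- Per-locus statistics exclude null/duplicated records from that locus'
  denominator only; microvariants are distinct allele classes.
- RST and networks use single-copy loci with microvariants rounded half-up
  to integer repeat scores; records with nulls/duplications at included
  loci are excluded and logged.
- PE/TPI/PIC follow STRAF-style conventions (Botstein PIC, PE =
  h²(1−2hH), TPI = 1/(2H) with H = Σp²); these are convention-dependent
  and documented in `ystrkit.forensic`.
- Display rounding is half-up (2 d.p. for percentages, 4 d.p. for
  diversities); raw values are always retained.

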