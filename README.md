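# minichrom

Read-coverage inference for maize mini chromosomes derived from the
supernumerary B chromosome — for geneticists and genome biologists who
need the comparative coverage analyses behind mini-chromosome
characterization as tested, reusable code that runs at desk scale.

Maize B chromosomes can break at the second pollen mitosis; the fragments
are usually lost, but occasionally a broken piece becomes a heritable
**mini chromosome** — which requires a working centromere, sometimes a
**de novo centromere** formed on sequence with no centromeric repeats at
all.  Three genome-wide coverage comparisons identify what such a mini
contains and where its centromere function lives:

1. **CNV breakpoint mapping.**  Unique 0-mismatch reads are counted per
   gene window and the library-normalized ratio of a derived line over the
   B73 control is formed,
   `r_w = (s_w/S)/(c_w/C)`, so hemizygous segments sit at 0.5 and
   trisomic segments at 1.5.  The junction is the exact single change
   point of the ratio — the split minimizing total within-segment sum of
   squared errors over all boundaries.
2. **B deficiency mapping.**  Reads that fail to map *uniquely* to the A
   genome are re-mapped to the B reference; unique B placements are
   counted in 1 kb windows.  Windows above the cross-homology background
   (estimated from a B-less control) are "covered", and the truncation
   point of a broken B is the change point of the covered indicator.
3. **CENH3 ChIP occupancy.**  Coverage of the centromeric histone CENH3
   relative to input chromatin classifies each line's B centromere as
   active / reduced / absent, and intervals of ≥3-fold enrichment present
   in exactly one line reveal de novo centromeres.

Because re-running the original terabase-scale experiment is not a unit
test, the package includes a first-class **synthetic study**: a scaled
reference model (10 kb of model sequence per real megabase) with CentC,
CRM, knob180 and ZmBs repeats laid out so that A/B cross-homology
multi-mapping arises mechanistically, six line karyotypes (B73, B73+B,
TB-9Sb, a 9-Bic-1 heterozygote, mini B1104, mini B496), and WGS/ChIP read
simulators with truth provenance.  See `docs/methods.md` for the model
and every threshold.

## Worked example

Run the whole six-line study end to end (simulation → trimming → mapping →
all three analyses; ~1 min on one CPU):

```bash
minichrom demo --seed 11 --out-dir demo_out
```

`demo_out/deficiency_calls.tsv` — where each derived line's B material ends:

```
line         status         point_paper_mb
9-Bic-1_het  breakpoint     2.09
miniB1104    breakpoint     2.09
miniB496     breakpoint     7.49
B73+B        no_deficiency
```

mini B1104 is truncated at the same ~2.1 Mb point as 9-Bic-1 (evidence it
is a 9-Bic-1 derivative) while mini B496 breaks at ~7.5 Mb; the intact-B
control shows no deficiency.

`demo_out/cnv_breakpoints.tsv` and `cnv_segments.tsv` — chromosome 9
dosage:

```
line         contig  point_paper_mb  mean_left  mean_right
9-Bic-1_het  chr9    3.05            0.523      1.016

line       direction  start_paper_mb  end_paper_mb  length_paper_kb
miniB1104  elevated   3.05            3.50          450
miniB496   elevated   9.50            9.65          150
```

The heterozygote's ratio steps from ~0.5 to ~1 at ~3 Mb (the 9S
translocation point); mini B1104 carries an extra copy of the ~500 kb
immediately distal of that junction, mini B496 an interstitial ~200 kb
piece in the ninth megabase.

`demo_out/b_occupancy.tsv` and `unique_domains.tsv` — where CENH3 sits:

```
line         score  label          line       start_mb  end_mb  width_kb
B73          1.00   absent         miniB1104  3.10      3.35    248
B73+B        10.40  active         miniB496   9.51      9.67    159
TB-9Sb       8.69   active
9-Bic-1_het  0.10   absent
miniB1104    2.77   reduced
miniB496     0.26   absent
```

Both minis have lost (mini B496) or largely lost (mini B1104) CENH3 at the
canonical B centromere, and each instead shows a CENH3 domain on its 9S
segment that no other line carries — de novo centromeres of ~250 kb and
~160 kb.

`demo_out/screen_report.tsv` reproduces the kernel-screen arithmetic,
e.g. `b_breakage  6/1412  0.42` — at least 0.42% of screened kernels
reflect breakage of the B chromosome itself.

Each stage is also exposed as its own subcommand
(`simulate-genome`, `simulate-reads`, `map`, `cnv`, `deficiency`, `chip`,
`screen-stats`) handing off through FASTA/FASTQ/SAM/BED/TSV files, and as
a library API (`minichrom.Study`, `run_wgs`, `run_chip`,
`localize_breakpoint`, `call_b_breakpoint`, `call_unique_domains`, ...).

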