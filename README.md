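# stopin

A design and in-silico validation toolkit for generating putative null
mutants in *C. elegans* (and other genetic models) by CRISPR/Cas9 knock-in
of a universal 43-nt **STOP-IN cassette**:

```
5'-GGGAAGTTTGTCCAGAGCAGAGGTGACTAAGTGATAAGCTAGC-3'
   |— exogenous Cas9 site —||—— stops ——||NheI|
```

Inserted anywhere in coding sequence, the cassette introduces stop codons in
all three reading frames (2, 2, and 1 stops in frames 1, 2, 3) and — because
43 ≡ 1 (mod 3) — a frameshift that disrupts the protein even under stop
readthrough. It also installs an exogenous Cas9 target for later reversion
or tagging, an NheI site for RFLP genotyping, and a binding site for one
universal inner PCR primer (`GCTTATCACTTAGTCACCTCTGCTC`).

The toolkit is for geneticists planning such edits: it picks guide sites,
writes the single-stranded repair oligos, proves the predicted edit is a
null on every isoform, designs the PCR screen, and reproduces the published
screen-efficiency statistics.

## What it does

* **Guide selection** — scans a gene for 20-nt protospacers with an NGG PAM
  on either strand, keeps sites whose blunt cut (3 bp 5' of the PAM, between
  protospacer bases 17/18) falls inside coding sequence, and ranks them by
  position in the spliced CDS, preferring early exons shared by all
  isoforms.
* **Repair-oligo design** — builds the ~113-nt ssODN (35-nt homology arms
  flanking the cut + 43-nt cassette) on the PAM strand, orienting the
  payload so the gene's sense strand always acquires the cassette verbatim;
  also designs 71-nt wild-type reversion oligos with their companion crRNA
  (`GGGAAGTTTGTCCAGAGCAG`).
* **In-silico verification** — simulates perfect HDR, rebuilds every
  isoform's transcript, and reports the premature stop, frameshift,
  truncation fraction, destruction of the original Cas9 site, and
  installation of the exogenous site.
* **Genotyping assay** — chooses gene-specific outer primers (amplicon kept
  < 500 bp so the 43-bp shift resolves on a gel), simulates both screening
  PCRs and NheI digestion, and calls genotypes from band patterns.
* **Screen statistics** — recomputes per-gene and pooled knock-in
  efficiencies from the packaged 22-experiment screen table and the
  chi-square comparison of lethal vs non-lethal genes; prints the
  ribonucleoprotein injection recipes.
* **Synthetic fixtures** — deterministic toy genomes (FASTA + GFF3 +
  ground-truth manifest) exercising every strand/phase/isoform combination,
  so everything above is testable offline.

## Worked example

```bash
stopin fixtures --out fx --seed 9 --preset aex2   # synthetic aex-2-like locus
stopin design  --genome fx/fixture.fa --gff fx/fixture.gff3 --gene aex-2-like --top 1
stopin genotype --genome fx/fixture.fa --gff fx/fixture.gff3 --gene aex-2-like
```

The design step prints (columns abridged):

```
rank  crRNA                 pam  pam_strand  cut  cds_fraction  oligo_5to3
1     GATTCATTACTGCAGCGACA  TGG  +           762  0.3176        TTAACACAAAGTTTAAGAGATTCATTACTGCAGCG GGGAAGTTT...TAGC ACATGGGG...
```

i.e. the best guide cuts at 32% of the spliced CDS and the 113-nt oligo
carries the cassette between two 35-nt arms. The genotyping step then
reports:

```
WT outer product: 182 bp
KI outer product: 225 bp (+43)
wild-type:     outer [182]      inner []    -> wild-type
heterozygous:  outer [182, 225] inner [174] -> heterozygous
homozygous KI: outer [225]      inner [174] -> homozygous-candidate
```

matching the expected gel logic: the inner (cassette-specific) reaction
fires only on knock-in templates, and the outer pair shows the 43-bp shift.
`stopin stats` prints the screen table summary, ending in:

```
pooled: 46% (322/694)
lethal: 27% (72/267)
non-lethal: 59% (250/427)
chi-square = 65.88, p = 4.79e-16
```

## Layout

```
src/stopin/
  genome_model.py   FASTA/GFF3 I/O, intervals, spliced CDS + coordinate maps
  cassette.py       the cassette constant and frame/integrity analysis
  guides.py         protospacer-NGG scanning, cut geometry, ranking
  repair.py         knock-in and reversion ssODNs, simulated HDR
  verify.py         per-isoform null verification
  genotyping.py     outer-primer design, in-silico PCR, NheI RFLP, calls
  screen_stats.py   efficiency accounting, chi-square, injection recipes
  fixtures.py       deterministic synthetic genome generator
  cli.py            the `stopin` command
```

See `docs/methods.md` for the model, conventions, and limitations.
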