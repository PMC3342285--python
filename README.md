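# ryrseq

Clone-to-contig characterization of a full-length insect ryanodine receptor
(RyR) cDNA, built around the rice leaffolder (*Cnaphalocrocis medinalis*)
receptor **CmRyR** (GenBank JQ799046).

Insect RyRs are the molecular targets of the diamide insecticides, and their
cDNAs — at ~15 kb among the largest ion-channel transcripts known — are
characterized by compiling overlapping RT-PCR/RACE clones rather than by
single-pass sequencing. `ryrseq` implements that entire computational
workflow as a tested, reusable library with a synthetic-data generator, so
every stage can be verified against planted ground truth:

* **assembly** — greedy maximal-overlap merging of clone sequences into a
  single contig; nucleotide disagreements between overlapping clones are
  collected as conflict records (candidate alleles or PCR errors).
* **annotation** — longest-ORF detection, translation, average protein mass,
  UTR composition (GC/AT%, TATA box, AAUAAA), and silent/missense
  classification of conflicts in the Table-of-polymorphisms convention
  (1-based ORF coordinates, A of the initiator ATG = 1; substitutions
  sharing a codon are evaluated jointly).
* **motifs** — pattern scanning (Walker-A P-loop `[GA]XXXXGK[ST]`, pore
  motif `GXRXGGGXGD`), PROSITE-style EF-hand detection, Kyte–Doolittle
  hydropathy TM prediction, and a validated domain track (MIR, RIH, SD,
  SPRY×3, RyR×4, RIH-associated).
* **comparative** — Needleman–Wunsch identity, p-distance matrices,
  Saitou–Nei neighbor joining with column-bootstrap supports, and a
  taxon-diagnostic residue scanner: columns where a focal clade
  (here, Lepidoptera) is monomorphic for one residue while all other taxa
  share a different one, with an explicit exception allowance.
* **splice** — alternative-exon discovery from clone pools (mutually
  exclusive pair a/b at IASI, optional exon c at IASII), degenerate primer
  design by IUPAC back-translation, in-silico diagnostic PCR, and per-pool
  exon-usage tables with exact binomial confidence intervals.
* **synthetic** — generates every fixture the pipeline consumes, with
  machine-readable truth files: the 15,773-nt transcript
  (289-nt 5′UTR + 15,264-nt ORF + 220-nt 3′UTR), a second haplotype carrying
  all 35 published substitutions, 16-fragment clone libraries, stage-specific
  splice pools, and a 31-sequence grouped MSA with planted diagnostic columns.

## Worked example

```python
import ryrseq as R
from ryrseq import studydata as S, synthetic

# full-length fixture transcript, fragmented and reassembled
reference = R.cmryr_reference(seed=0)
clones, _ = R.make_clone_library(reference, 16, seed=1)
contig = R.assemble_clones(clones)
ann = R.find_orf(contig.seq)
print(len(contig.seq), ann.end - ann.start, len(ann.protein))
# 15773 15264 5087

# plant the 35 published substitutions into a second haplotype and
# rediscover them as overlap conflicts
ref2, variant, _ = R.plant_substitutions(reference, S.SUBSTITUTIONS)
lib, _ = R.make_clone_library(ref2, 44, overlap_range=(40, 90), seed=2,
                              variant=variant)
_, polys = R.annotate_contig(R.assemble_clones(lib))
print(R.effect_tally(polys))
# {'total': 35, 'missense': 20, 'silent': 15, 'noncoding': 0}

# genotype splice pools purely by in-silico diagnostic PCR
exons = synthetic.cmryr_exon_sequences()
pools, _ = R.make_splice_pools(synthetic.cmryr_splice_pool_specs(0),
                               exons["a"], exons["b"], exons["c"], reference)
panel = R.cmryr_panel()
calls = {n: [R.classify_clone(c, panel) for c in cl] for n, cl in pools.items()}
print({(r.pool, r.exon): r.frequency for r in R.exon_usage(calls)
       if r.exon == "b" and r.pool in ("P", "AB")})
# {('P', 'b'): 30, ('AB', 'b'): 48}
```

The contig length (15,773 bp), ORF length (15,264 nt), protein size
(5,087 aa), polymorphism split (35 sites = 20 missense + 15 silent) and
exon-b usage (30% pupal, 48% adult body) match the published
characterization of CmRyR.

A `ryrseq` command-line tool wraps the same stages
(`simulate`, `assemble`, `annotate`, `motifs`, `compare`,
`diagnostic-sites`, `splice`); run `ryrseq --help`.

## Layout

```
src/ryrseq/
  synthetic.py    fixture generation + truth files
  assembly.py     overlap assembly, conflict detection
  annotation.py   ORF/UTR annotation, mass, conflict classification
  motifs.py       motif/EF-hand/TM scanning, domain track
  comparative.py  identity, p-distance, NJ + bootstrap, diagnostic sites
  splice.py       primer design, in-silico PCR, exon usage
  studydata.py    published CmRyR values (substitution table, primers,
                  domain coordinates, pool counts)
  cli.py          command-line interface
docs/methods.md   model/procedure notes and design choices
```
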