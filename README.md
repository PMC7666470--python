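# insertag

Discovery, sequence tracing, and genotyping of **non-reference insertion
structural variants** (> 50 bp) from short-read paired-end data.

Insertions are the hardest structural variant class to call against a linear
reference: reads originating from sequence the reference lacks are simply
unalignable, so the variant is invisible to reference-projection methods.
`insertag` targets exactly this blind spot with a three-stage pipeline aimed
at population-scale short-read datasets:

1. **Discovery** — read pairs with one confidently anchored end and one
   unmapped or discordantly mapped end are clustered per strand and locally
   assembled (De Bruijn) into *insertion-tags*: contigs consisting of a
   flanking reference segment, a breakpoint, and a partial inserted
   sequence. A left-flank and a right-flank tag within the insert-size
   window, with agreeing breakpoints, jointly evidence one insertion event.
2. **Tracing** — the full inserted sequence is inferred from *other*
   genomes: the reference flanks locate the syntenic locus in each target
   genome, the intervening target sequence is the candidate insertion, and
   it is accepted when the partial tag sequences align to its ends.
   Insertions traced to non-human primate genomes are retained **ancestral
   sequences** (the reference carries a deletion); insertions found only in
   other human assemblies or unmapped-contig databases are **novel
   insertions** postdating the human–primate split.
3. **Genotyping** — for each catalogued variant, a reference allele and an
   insertion allele are built around the breakpoint; raw reads are aligned
   to both, counted for the allele they unequivocally support at a junction,
   and the biallelic genotype follows the supporting read-depth ratio
   r = n_alt/(n_ref + n_alt): r ≤ 0.2 → 0/0, r ≥ 0.8 → 1/1, otherwise 0/1
   (undetermined below depth 4).

Around the core the package ships a mutational-mechanism classifier
(VNTR → NAHR → TE → NH priority cascade on breakpoint sequence features; TE
requires > 80% retroelement content), a full simulation benchmark (synthetic
genomes with near-identical repeat families, implanted insertions, wgsim-like
read simulation, and sensitivity/FDR scoring with breakpoint-gap < 100 bp and
≥ 50%-aligned matching rules), and population summaries: allele frequencies,
per-individual inserted-sequence load, and Nei's pairwise
F_ST = (H_T − H_S)/H_T.

See `docs/methods.md` for the model, parameter defaults, and limitations.

## Worked example

Simulate a small benchmark, run discovery on the unique-insertion condition,
and score it:

```bash
insertag evaluate --workdir sim --seed 1 --genome-length 1000000 \
    --n-insertions 20 --condition unique --out-json metrics.json
cat metrics.json
```

Output (numbers from this command on one run):

```json
{"unique": {"sensitivity": 0.8, "fdr": 0.0}}
```

meaning 16 of the 20 implanted insertions were recovered as paired
insertion-tags with breakpoints within 100 bp of the implant site and
sequence-confirmed partials, and no called insertion failed to match an
implant. The misses are small implants (~150 bp) whose junctions produce
almost no unmapped reads at 30× — see the limitations section of the
methods note.

The equivalent library calls:

```python
from insertag import benchmark
cfg = benchmark.BenchmarkConfig(genome_length=1_000_000, n_insertions=20)
inputs = benchmark.prepare_inputs("sim", seed=1, config=cfg)
metrics = benchmark.run_condition(inputs, unique=True)
print(metrics.sensitivity, metrics.fdr, metrics.breakpoint_gaps[:5])
```

For real data the stages run separately: `insertag discover` (BAM +
reference → paired-tag TSV/FASTA), `insertag trace` (tags + target genome
FASTAs → sequence-resolved catalogue VCF with SVLEN/TRACESRC/ANCSTATE/
CONCORD INFO keys), `insertag genotype` (catalogue + sample BAMs →
multi-sample VCF with GT and AD), and `insertag popgen` (genotype VCF +
sample–population TSV → AF/load/F_ST tables).

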