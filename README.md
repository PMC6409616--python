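# cugkit

Tools for bringing transformation genetics to yeasts that have reassigned
the CUG codon.

Most nuclear genomes translate CUG as leucine, but the CUG-Ser clades of
budding yeasts (which include *Candida albicans* and the Metschnikowiaceae)
read it as serine, and the CUG-Ala clade as alanine. A selectable-marker
gene written for a standard-code host therefore mistranslates in these
species at every CUG codon — often the reason transformation simply yields
no colonies. `cugkit` implements the computational side of solving that
problem:

* **Genetic codes & degeneracy** (`cugkit.genetic_codes`) — complete
  64-codon tables for the standard, CUG-Ser and CUG-Ala nuclear codes;
  translation; verification that a CDS is *degenerate* (translates
  identically) across all of them. A CDS is degenerate across the three
  codes iff it contains no CUG codon.
* **Codon usage & marker recoding** (`cugkit.codon_usage`,
  `cugkit.recoder`) — build relative-synonymous-usage tables from reference
  genes, then recode a marker ORF: every in-frame CTG → TTG (silent under
  the standard code), followed by one-amino-acid-to-one-codon optimization
  toward the host's preferred codons, capped at 25 changes by default.
  Controls with the original CUG codons reintroduced are one call away, and
  every substitution is logged and replayable.
* **CUG-decoding inference** (`cugkit.code_inference`) — align a query
  protein (CTG positions masked) against a homolog profile and score which
  residue the conserved columns demand at the CUG positions:
  `score(code) = Σ log[(count(residue) + 1) / (depth + 20)]`, with a
  2-nat decision margin; the caller gets `cug_ser`, `cug_leu`, `cug_ala`,
  or `indeterminate` — never a guess.
* **tRNA classification** (`cugkit.trna_classifier`) — annotate a
  CAG-anticodon tRNA (anticodon loop, closing stem, discriminator base,
  variable arm) and classify it by identity elements: G73 → serine-type,
  A73 → leucine-type.
* **Insertion-site mapping** (`cugkit.insertion_mapper`) — simulate the
  restriction-digest / self-ligation / inverse-PCR protocol used to find
  where a cassette integrated, and map the resulting junction sequence back
  to the assembly by exact flank matching.
* **Synthetic fixtures** (`cugkit.synthetic_data`) — seeded generators for
  genomes, ORFs, usage distributions, homolog families with a planted true
  code, tRNAs with planted identity elements, and planted-cassette
  insertion scenarios, each with a machine-readable truth record.

## Worked example

Recode a donor ORF for a CUG-Ser host and verify degeneracy:

```python
from cugkit import (
    count_codon, optimize_one_to_one, replace_ctg_with_ttg, translate,
)
from cugkit.synthetic_data import random_orf, synthetic_usage_table

donor = random_orf(500, seed=1, id="donor")       # 500-codon ORF
table = synthetic_usage_table(seed=1)              # host usage table

step1 = replace_ctg_with_ttg(donor)
recoded = optimize_one_to_one(step1.output, table) # cap 25, CTG forbidden

print("CUG codons in donor:  ", count_codon(donor, "CTG"))
print("CUG codons recoded out:", len(step1.substitutions))
print("usage optimizations:   ", recoded.n_optimization_changes)
print("degenerate:", recoded.verification.is_degenerate)
print("protein preserved:",
      translate(recoded.output, "cug_ser") == translate(donor, "standard"))
```

Output:

```
CUG codons in donor:   8
CUG codons recoded out: 8
usage optimizations:    25
degenerate: True
protein preserved: True
```

The donor happened to carry 8 CUG codons; all were silently replaced, the
optimizer then applied exactly its 25-change budget, and the result
translates to the identical protein under the standard, CUG-Ser and
CUG-Ala codes.

The same operations are available from a shell:

```sh
cugkit simulate --kind insertion --seed 5 --outdir fixtures/
cugkit optimize --in genes.fasta --usage table.tsv --max-changes 25 \
    --target-code cug_ser --out optimized.fasta --report report.tsv
cugkit map-insert --junction amplicon.fasta --genome assembly.fasta \
    --cassette cassette.fasta --out call.tsv
```

Run `cugkit --help` for the full subcommand list (`translate`, `usage`,
`optimize`, `hooks`, `infer-code`, `classify-trna`, `digest`, `ipcr-sim`,
`map-insert`, `simulate`).

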