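"""Assign Sequence Ontology effect terms to SNPs from gene models.

Coding effects come from strand-aware codon comparison against the
reference; splice, UTR, intron, upstream/downstream and intergenic calls
follow conventional boundary rules (donor/acceptor = first/last 2 intronic
bases; 5 kb up/downstream distance).
"""

from pathlib import Path
from tempfile import TemporaryDirectory

from paralogsift import SimConfig, simulate
from paralogsift.annotation import annotate_site, effect_summary, read_gff3
from paralogsift.pipeline import run_all

res = simulate(SimConfig(seed=42))
run = run_all(res.callset_a, res.callset_b, res.sheet, res.build,
              sequences=res.sequences)

with TemporaryDirectory() as tmp:
    paths = res.write(tmp)  # includes toy gene models (genes.gff3)
    models = read_gff3(paths["genes"])

records = []
for site in run.retained:
    records.extend(annotate_site(site, models, res.sequences))

print(f"{len(records)} predicted effects for {len(run.retained)} SNPs")
print("(a SNP near several genes or transcripts yields several effects)\n")
print(f"{'SO term':<48}{'impact':<10}{'effects':>8}")
for term, impact, n in effect_summary(records):
    if n:
        print(f"{term:<48}{impact:<10}{n:>8}")
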