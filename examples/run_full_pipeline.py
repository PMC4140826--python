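"""Run the whole pipeline on a compact synthetic study.

Generates every input file (gene/lncRNA BED, transcript FASTA, variant table,
evidence tables, RepeatMasker-style repeats, FPKM matrix), runs
classify -> map -> score -> rank -> stats -> expression, and prints the
per-disease funnel and the top ranked variants.
"""

import tempfile
from pathlib import Path

from lncsnp.pipeline import PipelineConfig, run_pipeline
from lncsnp.synthetic_data import SimulationConfig, generate_fixture_bundle

sim = SimulationConfig(seed=42, n_genes=24, n_lncs=60, n_variants=150,
                       n_repeats=80, n_planted_disruptive=2, frac_in_lnc=0.05)
workdir = Path(tempfile.mkdtemp())
bundle = generate_fixture_bundle(sim)
paths = bundle.write(workdir / "inputs")

cfg = PipelineConfig(**{k: str(v) for k, v in paths.items()},
                     out_dir=str(workdir / "out"), n_background=49, seed=7)
result = run_pipeline(cfg)

print(f"outputs written to {workdir / 'out'}")
print(f"planted structure-disruptive variants: {bundle.truth['disruptive_variants']}")
for disease in sorted(result.ranked):
    n_assigned = len(result.assignments[disease])
    n_scored = len(result.disruption[disease])
    n_ranked = len(result.ranked[disease])
    print(f"\n{disease}: {n_assigned} mapped assignments -> {n_scored} scored "
          f"-> {n_ranked} significant & ranked")
    print(result.ranked[disease].head(5).to_string(index=False))

# Each disease funnel narrows from nominally significant variants mapped into
# loci-associated lncRNAs, to exonic variants scored for structure disruption,
# to those with empirical p <= 0.2 ranked by regulatory / eQTL / selection /
# structural evidence. The planted stem-breaking variants surface in the
# ranked tables.
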