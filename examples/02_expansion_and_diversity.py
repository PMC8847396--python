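"""Clonal expansion structure and Shannon evenness across conditions.

A steep clone-size law (acute-like, alpha=3.0) yields a flat repertoire of
mostly singletons; a shallow law (chronic/latent-like, alpha=1.8) yields
heavy clonal expansion and lower evenness.
"""

from clonoscope.clonotype import build_clones, clone_fraction_table, top_clones
from clonoscope.diversity import diversity_table
from clonoscope.synthetic_data import default_cohort_config, generate_cohort
from clonoscope.vdj_io import assemble_cells, contigs_from_frame

cohort = generate_cohort(default_cohort_config(seed=7, n_clones=150))
reps = []
for sid, contigs in cohort.contigs.items():
    cells, _ = assemble_cells(contigs_from_frame(contigs, "tenx_csv", sid))
    reps.append(build_clones(cells, cohort.truths[sid].group_label, sample_id=sid))

print(diversity_table(reps).to_string(index=False))
# evenness near 1 = polyclonal (acute-like); lower = dominated by expanded
# clones (chronic/latent-like), mirrored by the singleton fraction

rep = next(r for r in reps if r.group_label == "latent")
print(f"\ntop 5 clones of {rep.sample_id} (fraction of repertoire):")
table = clone_fraction_table(rep).head(5)
print(table.to_string(index=False))
expanded = [c for c in rep.clones if c.expansion_class == "expanded"]
print(f"{len(expanded)}/{rep.richness} clones expanded (>= 2 cells)")
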