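"""Box-Cox + Welch + Storey differential expression on a planted study.

Simulates a 16-tumor vs 16-normal microarray panel with 10 planted
differential pairs at Cohen's d = 2, runs the per-feature engine, and
prints the top of the DE table.  Lambda near 0 shows the Box-Cox step
recovering the log scale of the log-normal intensities.
"""

from lncolink import (
    CATEGORIES, GenomeSpec, StudySpec,
    generate_expression_study, generate_transcript_pairs, run_de,
)
from lncolink.diffexpr import de_table

pairs = generate_transcript_pairs(
    GenomeSpec(counts_per_category={c: 5 for c in CATEGORIES}, seed=8)
)
mrna_study, lnc_study, truth = generate_expression_study(
    pairs, StudySpec(n_de_pairs=10, effect_size=2.0, seed=8)
)

records = run_de(mrna_study)
table = de_table(records)
planted = set(truth[truth.role == "mrna"].feature_id)

print(table.head(12).to_string(index=False,
      formatters={"lambda": "{:.2f}".format, "p": "{:.2e}".format,
                  "q": "{:.2e}".format}))
n_sig = (table.q < 0.05).sum()
hits = table[table.q < 0.05].feature_id.isin(planted).sum()
print(f"\n{n_sig} features at q < 0.05; {hits} of them are planted "
      f"({len(planted)} planted in total).")
print("mean_tumor/mean_normal are on the Box-Cox-transformed scale; "
      "direction 'up' means higher in tumor.")
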