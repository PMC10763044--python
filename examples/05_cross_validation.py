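"""Run the full pipeline under fivefold cross-validation on a planted study.

Writes the study to scratch/, runs similarity -> attributes -> multiplex
embedding -> gradient-boosted classification with per-fold embedding
retraining, and prints the evaluation summary.
"""

from smireg import PipelineConfig, SyntheticConfig, run_pipeline
from smireg.gatne import GatneConfig
from smireg.pipeline import LineParams
from smireg.synthetic import write_study

paths = write_study(SyntheticConfig(n_sm=24, n_mirna=16, n_edges_per_relation=80, seed=3),
                    "scratch/example_study")
config = PipelineConfig(
    fingerprints=str(paths["fingerprints"]),
    mirna_fasta=str(paths["mirna"]),
    edges=str(paths["edges_up"]),
    relation="up",
    seed=3,
    line=LineParams(dim=16, epochs=20),
    gatne=GatneConfig(walks_per_vertex=5, walk_length=8, window=3,
                      negatives=3, epochs=1, batch_size=256),
    classifier_params={"n_estimators": 100},
)
report = run_pipeline(config, outdir="scratch/example_run")
for metric in report.METRICS:
    print(f"{metric:5s} {report.mean(metric):.4f} +/- {report.sd(metric):.4f}")
# Mean +/- sd over the five folds; AUC well above 0.5 means the pipeline
# recovers the planted regulation signal from held-out pairs.
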