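import sys
from dataclasses import replace
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/_oracles importable

from smireg.gatne import GatneConfig
from smireg.pipeline import PipelineConfig, PipelineRun, run_pipeline
from smireg.synthetic import SyntheticConfig, write_study


@pytest.fixture(scope="session")
def default_study(tmp_path_factory):
    """The default planted study written to disk, plus a pipeline config for it."""
    outdir = tmp_path_factory.mktemp("study")
    paths = write_study(SyntheticConfig(), outdir)
    config = PipelineConfig(
        fingerprints=str(paths["fingerprints"]),
        mirna_fasta=str(paths["mirna"]),
        edges=str(paths["edges_up"]),
        relation="up",
        seed=7,
    )
    return {"paths": paths, "config": config}


@pytest.fixture(scope="session")
def tiny_study(tmp_path_factory):
    """A small, fast study plus a lightweight pipeline config for smoke tests."""
    outdir = tmp_path_factory.mktemp("tiny")
    cfg = SyntheticConfig(n_sm=24, n_mirna=16, n_edges_per_relation=80, seed=11)
    paths = write_study(cfg, outdir)
    config = PipelineConfig(
        fingerprints=str(paths["fingerprints"]),
        mirna_fasta=str(paths["mirna"]),
        edges=str(paths["edges_up"]),
        relation="up",
        seed=11,
        classifier_params={"n_estimators": 60},
        gatne=GatneConfig(walks_per_vertex=5, walk_length=8, window=3,
                          negatives=3, epochs=1, batch_size=256),
    )
    from smireg.pipeline import LineParams

    config = replace(config, line=LineParams(dim=16, epochs=15))
    return {"paths": paths, "config": config, "synthetic": cfg}


@pytest.fixture(scope="session")
def ablation_reports(default_study):
    """Cross-validation reports for the full model, both ablations and the
    label-shuffled control on the default planted study (shared seeds)."""
    reports = {}
    for mode in ("full", "gatne_only", "attrs_only"):
        reports[mode] = run_pipeline(replace(default_study["config"], mode=mode))
    reports["shuffled"] = PipelineRun(default_study["config"]).cross_validate(shuffle_labels=True)
    return reports
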