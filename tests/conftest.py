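import numpy as np
import pytest
from hypothesis import settings

import radstroke as rs

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def tiny_reports():
    return [
        rs.Report("r1", "p1", "CT", None, "No evidence of acute infarct."),
        rs.Report("r2", "p1", "MRI", None,
                  "Restricted diffusion in the left middle cerebral artery territory."),
        rs.Report("r3", "p2", "CTA", None,
                  "Encephalomalacia consistent with chronic infarct."),
    ]


@pytest.fixture
def tiny_labels():
    return [
        rs.LabelSet("r1", 0, 0, 0),
        rs.LabelSet("r2", 1, 1, 1),
        rs.LabelSet("r3", 1, 0, 0),
    ]


@pytest.fixture
def reports_csv(tmp_path, tiny_reports):
    path = tmp_path / "reports.csv"
    rs.write_reports(tiny_reports, path)
    return path


@pytest.fixture
def labels_csv(tmp_path, tiny_labels):
    path = tmp_path / "labels.csv"
    rs.write_labels(tiny_labels, path)
    return path


@pytest.fixture
def small_embedding():
    rng = np.random.default_rng(42)
    tokens = ["acute", "chronic", "infarct", "mca", "no", "stroke"]
    return rs.EmbeddingFile(tokens=tokens, vectors=rng.normal(size=(len(tokens), 5)))


@pytest.fixture(scope="session")
def default_corpus():
    """One shared default-condition synthetic corpus for slower tests."""
    reports, labels = rs.generate_reports(rs.GeneratorConfig(seed=11))
    docs = rs.preprocess_corpus(reports)
    return reports, labels, docs
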