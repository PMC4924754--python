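import numpy as np
import pandas as pd
import pytest

from lncarray import (
    AnnotationConfig,
    ExpressionMatrix,
    SampleMetadata,
    StudyConfig,
    generate_annotation,
    generate_expression,
)


def make_matrix(values: np.ndarray, prefix: str = "F", level: str = "lncRNA") -> ExpressionMatrix:
    m, n = values.shape
    return ExpressionMatrix(
        pd.DataFrame(
            values,
            index=[f"{prefix}{i:04d}" for i in range(m)],
            columns=[f"s{j:04d}" for j in range(n)],
        ),
        level=level,
    )


def make_metadata(entity_counts: dict[str, int], n_batches: int = 1) -> SampleMetadata:
    rows = []
    i = 0
    for entity, count in entity_counts.items():
        for _ in range(count):
            i += 1
            rows.append(
                {"sample_id": f"s{i - 1:04d}", "entity": entity,
                 "batch": f"b{(i - 1) % n_batches}"}
            )
    return SampleMetadata(pd.DataFrame(rows).set_index("sample_id"))


@pytest.fixture(scope="session")
def default_study():
    """One default synthetic study shared by read-only tests."""
    cfg = StudyConfig(annotation=AnnotationConfig(multi_hit_fraction=0.05))
    transcripts, probes = generate_annotation(cfg.annotation, seed=11)
    matrix, metadata, truth = generate_expression(transcripts, probes, cfg, seed=11)
    return {
        "config": cfg,
        "transcripts": transcripts,
        "probes": probes,
        "matrix": matrix,
        "metadata": metadata,
        "truth": truth,
    }
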