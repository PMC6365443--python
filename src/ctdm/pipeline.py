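"""Convenience orchestration: symmetrize -> GPA (-> slide) -> scores."""

from __future__ import annotations

import numpy as np

from .landmark_io import LandmarkSchema, ShapeSample
from .superimposition import GPAResult, gpa, slide_semilandmarks, symmetrize_sample
from .typicality import TypicalityScores, ctdm_scores

__all__ = ["superimpose_sample", "score_sample"]


def superimpose_sample(
    sample: ShapeSample,
    schema: LandmarkSchema | None = None,
    symmetrize: bool = True,
    slide: bool = False,
    tol: float = 1e-10,
    max_slide_cycles: int = 5,
) -> GPAResult:
    """Run the standard superimposition chain on a sample."""
    schema = schema or sample.schema
    work = sample
    if symmetrize:
        work = symmetrize_sample(sample, schema)
    result = gpa(work, tol=tol)
    if slide:
        if schema is None or not schema.curves:
            raise ValueError("sliding requires a schema with curves")
        result = slide_semilandmarks(result, schema, max_cycles=max_slide_cycles)
    return result


def score_sample(
    sample: ShapeSample,
    group_a: str,
    group_b: str,
    schema: LandmarkSchema | None = None,
    symmetrize: bool = True,
    slide: bool = False,
    origin: str = "midpoint",
    metric: str = "tangent-euclidean",
    tol: float = 1e-10,
) -> tuple[GPAResult, TypicalityScores]:
    """Superimpose a labelled sample and score it along the between-group axis."""
    result = superimpose_sample(
        sample, schema=schema, symmetrize=symmetrize, slide=slide, tol=tol
    )
    labels = np.asarray(sample.groups, dtype=object)
    scores = ctdm_scores(result, labels, group_a, group_b, origin=origin, metric=metric)
    return result, scores
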