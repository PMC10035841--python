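"""Expression-similarity candidate-gene screen.

Ranks genes by similarity of their developmental expression time course to a
reference receptor profile (the screen that surfaced *gukh* and *fra* as
DPP-receptor-like genes), then filters candidates by functional-annotation
keywords (cell migration / cell adhesion / cytoskeleton regulation) and a
D/V-asymmetric-expression flag.

The default similarity is 100 × Pearson correlation of log(1+x)-transformed
profiles — scale-free, so any common positive rescaling of the matrix leaves
the ranking unchanged; cosine and normalized-Euclidean alternatives are
selectable and recorded in the output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

DEFAULT_KEYWORDS = frozenset({"cell migration", "cell adhesion", "cytoskeleton regulation"})
METRICS = ("pearson_log", "cosine", "euclidean")


@dataclass(frozen=True)
class ScreenHit:
    gene: str
    similarity: float  # percent, in [-100, 100] for the default metric
    rank: int
    passed_annotation: bool
    passed_dv: bool

    @property
    def is_candidate(self) -> bool:
        return self.passed_annotation and self.passed_dv


def similarity_score(profile, reference, metric: str = "pearson_log") -> float:
    """Similarity percent between two expression profiles.

    ``pearson_log``: 100 × Pearson r of log1p profiles (default);
    ``cosine``: 100 × cosine similarity; ``euclidean``:
    100 × (1 − ‖a−b‖ / (‖a‖+‖b‖)).  Constant profiles are undefined under
    Pearson and raise.
    """
    a = np.asarray(profile, dtype=float)
    b = np.asarray(reference, dtype=float)
    if a.shape != b.shape:
        raise ValueError("profiles must have equal length")
    if metric == "pearson_log":
        la, lb = np.log1p(a), np.log1p(b)
        if la.std() == 0 or lb.std() == 0:
            raise ValueError("constant profile: Pearson correlation undefined")
        return float(100.0 * np.corrcoef(la, lb)[0, 1])
    if metric == "cosine":
        na, nb = np.linalg.norm(a), np.linalg.norm(b)
        if na == 0 or nb == 0:
            raise ValueError("zero profile: cosine similarity undefined")
        return float(100.0 * (a @ b) / (na * nb))
    if metric == "euclidean":
        denom = np.linalg.norm(a) + np.linalg.norm(b)
        if denom == 0:
            raise ValueError("zero profiles: normalized distance undefined")
        return float(100.0 * (1.0 - np.linalg.norm(a - b) / denom))
    raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")


def _keywords_of(ann: pd.DataFrame, gene: str) -> set[str]:
    raw = ann.loc[gene, "keywords"] if gene in ann.index else ""
    if isinstance(raw, float) and np.isnan(raw):
        return set()
    return {w.strip() for w in str(raw).split(";") if w.strip()}


def rank_candidates(
    matrix: pd.DataFrame,
    reference_gene: str,
    annotations: pd.DataFrame | None = None,
    keywords: frozenset[str] | set[str] = DEFAULT_KEYWORDS,
    require_dv: bool = True,
    metric: str = "pearson_log",
) -> list[ScreenHit]:
    """Score every gene against a reference gene's profile and rank descending.

    ``matrix`` is genes × stages (non-negative); ``annotations`` indexes genes
    with a ``keywords`` column (";"-separated) and a ``dv_asymmetric`` flag.
    Ties are broken stably by gene id.  All scored genes are returned with
    their filter flags; the final candidate list is
    ``[h for h in hits if h.is_candidate]``.
    """
    if reference_gene not in matrix.index:
        raise KeyError(f"reference gene {reference_gene!r} not in matrix")
    if (matrix.to_numpy() < 0).any():
        raise ValueError("expression values must be non-negative")
    ref = matrix.loc[reference_gene].to_numpy(dtype=float)
    scores: list[tuple[str, float]] = []
    for gene in matrix.index:
        try:
            s = similarity_score(matrix.loc[gene].to_numpy(dtype=float), ref, metric=metric)
        except ValueError:
            continue  # constant/zero profiles are unscoreable, skip
        scores.append((str(gene), s))
    scores.sort(key=lambda gs: (-gs[1], gs[0]))
    hits = []
    kw = set(keywords)
    for rank, (gene, s) in enumerate(scores, start=1):
        if annotations is not None:
            passed_kw = bool(kw & _keywords_of(annotations, gene))
            dv = bool(annotations.loc[gene, "dv_asymmetric"]) if gene in annotations.index else False
        else:
            passed_kw = True
            dv = True
        hits.append(
            ScreenHit(
                gene=gene,
                similarity=s,
                rank=rank,
                passed_annotation=passed_kw,
                passed_dv=dv or not require_dv,
            )
        )
    return hits


def candidates(hits: list[ScreenHit]) -> list[ScreenHit]:
    """Genes passing both the keyword and the D/V-asymmetry filters."""
    return [h for h in hits if h.is_candidate]


def hits_to_frame(hits: list[ScreenHit], metric: str = "pearson_log") -> pd.DataFrame:
    """Tabulate screen hits (the metric is recorded as output metadata)."""
    df = pd.DataFrame(
        {
            "gene": [h.gene for h in hits],
            "similarity_percent": [h.similarity for h in hits],
            "rank": [h.rank for h in hits],
            "passed_annotation": [h.passed_annotation for h in hits],
            "passed_dv": [h.passed_dv for h in hits],
            "candidate": [h.is_candidate for h in hits],
        }
    )
    df.attrs["metric"] = metric
    return df
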