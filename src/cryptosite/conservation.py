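"""Evolutionary conservation of phosphosite alignment columns.

Conservation is expressed as an *entropic score* (ES): the Shannon entropy
of the residue frequencies in an alignment column, normalized by log(K)
where K is the size of a fixed symbol alphabet (20 standard amino acids, the
gap symbol, and a pooled ambiguity symbol 'X'; K = 22 by default).  A column
in which all sequences carry the same residue scores 0; a column where all K
symbols are equally frequent scores 1.  The score is independent of the
logarithm base because it is a ratio.

Also provided: the interquartile-range filter used to drop low-completeness
proteomes from the orthogroup analysis (BUSCO score below Q1 - 1.5 IQR),
Cohen's d as the effect size for comparing ES distributions, and a summary
comparison of cryptic versus non-cryptic ES sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, DataError
from .structio import Alignment

__all__ = [
    "Alignment", "EsParams", "map_position_to_column", "entropic_score",
    "cohens_d", "busco_iqr_filter", "compare_es_distributions",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: ambiguity / rare-letter codes pooled into 'X'
POOLED_TO_X = set("BZUO")


@dataclass
class EsParams:
    """Alphabet over which column frequencies are taken; K is its size."""

    alphabet: tuple[str, ...] = field(default_factory=lambda: tuple(AMINO_ACIDS) + ("-", "X"))

    def __post_init__(self) -> None:
        if self.K < 2:
            raise ConfigError("alphabet must have at least two symbols")
        if "-" not in self.alphabet:
            raise ConfigError("alphabet must contain the gap symbol")

    @property
    def K(self) -> int:
        return len(self.alphabet)


def map_position_to_column(aln: Alignment, human_pos: int) -> int:
    """0-based alignment column holding the human_pos-th (1-based) residue
    of the human row."""
    row = aln.row(aln.human_id)
    nongap = np.flatnonzero(row != "-")
    if not 1 <= human_pos <= len(nongap):
        raise DataError(
            f"position {human_pos} beyond the human sequence's ungapped length {len(nongap)}")
    return int(nongap[human_pos - 1])


def entropic_score(column: np.ndarray | list[str] | str,
                   params: EsParams | None = None) -> float:
    """Normalized column entropy: S = -sum_a p_a ln p_a / ln K in [0, 1]."""
    params = params or EsParams()
    chars = np.asarray(list(column) if isinstance(column, str) else column, dtype="U1")
    if chars.size == 0:
        raise DataError("empty alignment column")
    pooled = np.where(np.isin(chars, sorted(POOLED_TO_X)), "X", chars)
    known = set(params.alphabet)
    pooled = np.where(np.isin(pooled, sorted(known)), pooled, "X")
    _, counts = np.unique(pooled, return_counts=True)
    p = counts / counts.sum()
    entropy = float(-(p * np.log(p)).sum())  # 0*ln0 never arises: counts > 0
    return entropy / np.log(params.K) + 0.0  # normalize -0.0


def cohens_d(x: np.ndarray | list[float], y: np.ndarray | list[float]) -> float:
    """Effect size (mean x - mean y) / pooled sample standard deviation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise DataError("Cohen's d needs at least two observations per group")
    n1, n2 = len(x), len(y)
    pooled_var = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2)
    if pooled_var == 0:
        raise DataError("Cohen's d undefined: zero pooled standard deviation")
    return float((x.mean() - y.mean()) / np.sqrt(pooled_var))


def busco_iqr_filter(scores: dict[str, float]) -> dict[str, float]:
    """Keep organisms whose completeness score is not an extreme low outlier.

    The cutoff is Q1 - 1.5 IQR with quartiles by linear interpolation;
    organisms strictly below the cutoff are dropped.
    """
    if len(scores) < 4:
        raise DataError("IQR filtering needs at least four organisms")
    values = np.array(list(scores.values()), dtype=float)
    q1, q3 = np.percentile(values, [25, 75])  # linear interpolation (type 7)
    cutoff = q1 - 1.5 * (q3 - q1)
    return {org: s for org, s in scores.items() if s >= cutoff}


def compare_es_distributions(cryptic_es: np.ndarray | list[float],
                             noncryptic_es: np.ndarray | list[float],
                             bin_width: float = 0.05) -> dict:
    """Summary comparison of two ES sets: medians, effect size, rank-sum test.

    Returns a dict with medians, their difference (cryptic - non-cryptic),
    Cohen's d, the Mann-Whitney U p-value, and a per-group histogram table.
    """
    x = np.asarray(cryptic_es, dtype=float)
    y = np.asarray(noncryptic_es, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise DataError("both ES sets must be non-empty")
    edges = np.arange(0.0, 1.0 + bin_width + 1e-9, bin_width)
    rows = []
    for name, values in (("cryptic", x), ("noncryptic", y)):
        counts, _ = np.histogram(np.clip(values, 0, 1 - 1e-12), bins=edges)
        for lo, hi, c in zip(edges[:-1], edges[1:], counts):
            rows.append({"group": name, "bin_lo": float(lo), "bin_hi": float(hi),
                         "count": int(c)})
    if np.array_equal(np.sort(x), np.sort(y)):
        p_value = 1.0
    else:
        p_value = float(stats.mannwhitneyu(x, y, alternative="two-sided").pvalue)
    try:
        d = cohens_d(x, y)
    except DataError:
        d = 0.0 if float(np.mean(x)) == float(np.mean(y)) else float("nan")
    return {
        "median_cryptic": float(np.median(x)),
        "median_noncryptic": float(np.median(y)),
        "median_difference": float(np.median(x) - np.median(y)),
        "cohens_d": d,
        "mannwhitney_p": p_value,
        "n_cryptic": len(x),
        "n_noncryptic": len(y),
        "histogram": pd.DataFrame(rows),
    }
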