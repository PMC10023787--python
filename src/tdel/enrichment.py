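"""Enrichment-fold statistics, hit ranking and resynthesis combinations.

The enrichment fold of a library member is its post-selection fraction
(count / total counts) divided by its pre-selection fraction. Because the
three sub-libraries are decoded independently, enrichment is computed per
channel (marginal per building block); joint (a, b, c) deconvolution is
not attempted — the encoding carries no code-joining information, so the
follow-up is a full factorial resynthesis of the top hits from each
channel (e.g. 3 x 5 x 3 = 45 candidate compounds).
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError
from .library import TDELibrary, TDELMember, combined_mass

SCATTER_COLUMNS = ["code_id", "post_count", "fold"]


def enrichment_fold(
    pre: Mapping[str, int],
    post: Mapping[str, int],
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per-code enrichment folds from pre- and post-selection counts.

    With pseudocount alpha and M codes:

        fold_i = ((post_i + a) / (T_post + a*M)) / ((pre_i + a) / (T_pre + a*M))

    The default alpha = 1 keeps folds finite at realistic sequencing depth
    where zero pre-counts are expected. With alpha = 0 a zero pre-count
    yields an infinite fold, kept and flagged (column ``infinite``) rather
    than dropped. The union of both code universes is used; codes absent
    from one sample count as zero.
    """
    if pseudocount < 0:
        raise ConfigError(f"pseudocount must be >= 0, got {pseudocount}")
    codes = sorted(set(pre) | set(post))
    if not codes:
        raise ConfigError("no codes in either count table")
    pre_counts = np.array([pre.get(c, 0) for c in codes], dtype=float)
    post_counts = np.array([post.get(c, 0) for c in codes], dtype=float)
    if np.any(pre_counts < 0) or np.any(post_counts < 0):
        raise ConfigError("counts must be >= 0")
    t_pre, t_post = pre_counts.sum(), post_counts.sum()
    if t_pre <= 0 or t_post <= 0:
        raise ConfigError("pre and post totals must be > 0")
    m = len(codes)
    a = pseudocount
    pre_frac = (pre_counts + a) / (t_pre + a * m)
    post_frac = (post_counts + a) / (t_post + a * m)
    with np.errstate(divide="ignore"):
        fold = post_frac / pre_frac
    df = pd.DataFrame(
        {
            "code_id": codes,
            "pre_count": pre_counts.astype(int),
            "post_count": post_counts.astype(int),
            "pre_fraction": pre_frac,
            "post_fraction": post_frac,
            "fold": fold,
            "infinite": ~np.isfinite(fold),
        }
    )
    df.attrs["pseudocount"] = a
    return df


def rank_hits(
    table: pd.DataFrame,
    min_post_count: int = 0,
    top_k: int | None = None,
) -> pd.DataFrame:
    """Filter and rank an enrichment table.

    Keeps rows with ``post_count >= min_post_count``, sorts by fold
    descending (infinite folds first), breaking ties by post_count
    descending then code_id ascending — fully deterministic.
    """
    if top_k is not None and top_k < 0:
        raise ConfigError("top_k must be >= 0")
    kept = table[table["post_count"] >= min_post_count].copy()
    kept = kept.sort_values(
        by=["fold", "post_count", "code_id"],
        ascending=[False, False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    if top_k is not None:
        kept = kept.head(top_k).reset_index(drop=True)
    return kept


def _hit_ids(hits) -> list[str]:
    if isinstance(hits, pd.DataFrame):
        return list(hits["code_id"])
    return list(hits)


def combination_matrix(
    hits_a,
    hits_b,
    hits_c,
    library: TDELibrary | None = None,
    linkage_correction: float = 0.0,
) -> pd.DataFrame:
    """Full factorial of selected hits: every (a, b, c) resynthesis candidate.

    Accepts id lists or ranked enrichment tables. With a library whose
    building blocks carry masses, a ``combined_mass`` column (additive,
    minus ``linkage_correction``) is included.
    """
    ids_a, ids_b, ids_c = _hit_ids(hits_a), _hit_ids(hits_b), _hit_ids(hits_c)
    for label, ids in (("A", ids_a), ("B", ids_b), ("C", ids_c)):
        if not ids:
            raise ConfigError(f"hit list {label} is empty")
    rows = []
    for a_id in ids_a:
        for b_id in ids_b:
            for c_id in ids_c:
                row = {"a_id": a_id, "b_id": b_id, "c_id": c_id}
                if library is not None:
                    row["combined_mass"] = combined_mass(
                        TDELMember(a_id, b_id, c_id), library, linkage_correction
                    )
                rows.append(row)
    columns = ["a_id", "b_id", "c_id"] + (["combined_mass"] if library is not None else [])
    return pd.DataFrame(rows, columns=columns)


def export_scatter(table: pd.DataFrame, path: str | Path | None = None) -> pd.DataFrame:
    """(post_count, fold) rows per member for enrichment-vs-count scatter plots."""
    scatter = table.loc[:, SCATTER_COLUMNS].copy()
    if path is not None:
        scatter.to_csv(path, index=False)
    return scatter


def read_scatter(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"code_id": str})


def channel_enrichment(
    pre_channel: Mapping[str, int],
    post_channel: Mapping[str, int],
    all_ids: Iterable[str] | None = None,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Enrichment over an explicit code universe (zero-filling unseen codes)."""
    if all_ids is not None:
        pre_channel = {i: pre_channel.get(i, 0) for i in all_ids}
        post_channel = {i: post_channel.get(i, 0) for i in all_ids}
    return enrichment_fold(pre_channel, post_channel, pseudocount)


def recovery_metrics(
    true_weights: Sequence[float],
    ids: Sequence[str],
    table: pd.DataFrame,
    top_true: int = 3,
    top_decoded: int = 5,
) -> dict[str, float]:
    """Compare decoded folds with true capture weights on one channel.

    Returns the Spearman rank correlation and the fraction of the
    ``top_true`` highest-true-weight members recovered in the decoded
    ``top_decoded``.
    """
    from scipy.stats import spearmanr

    w = pd.Series(np.asarray(true_weights, dtype=float), index=list(ids))
    folds = table.set_index("code_id")["fold"].reindex(w.index)
    rho = spearmanr(w.values, folds.values).statistic
    true_top = set(w.sort_values(ascending=False).index[:top_true])
    decoded_top = set(rank_hits(table, top_k=top_decoded)["code_id"])
    overlap = len(true_top & decoded_top) / max(len(true_top), 1)
    return {"spearman": float(rho), "top_recovery": float(overlap)}
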