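"""Cross-method cluster matching and similarity scoring.

The network community method and the variable-clustering method each
produce a top-3 list of feature clusters per cohort. The matcher searches
all (at most 3! = 6) one-to-one pairings and keeps the one maximizing the
total pairwise intersection; the similarity percentage is

    100 * |union of pairwise intersections| / |union of all features in
                                               both methods' top-3 lists|.

A per-cluster mean-Jaccard alternative is reported alongside. The matched
sets feed the similar / dissimilar / unique phenotype tables comparing
cohorts, and a logistic regression quantifies how the selected features
predict cohort membership.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .cohorts import FeatureMatrix
from .network import NetworkMetrics

logger = logging.getLogger(__name__)


@dataclass
class ClusterMatch:
    """Best one-to-one correspondence between two methods' top clusters."""

    clusters_a: list[list[str]]
    clusters_b: list[list[str]]
    assignment: list[tuple[int, int]]            # (index into a, index into b)
    pair_intersections: list[int]
    matched_variables: set[str]
    unmatched_a: set[str]
    unmatched_b: set[str]
    similarity_pct: float
    mean_jaccard_pct: float

    def to_dict(self) -> dict:
        return {
            "clusters_a": [sorted(c) for c in self.clusters_a],
            "clusters_b": [sorted(c) for c in self.clusters_b],
            "assignment": [list(p) for p in self.assignment],
            "pair_intersections": self.pair_intersections,
            "matched_variables": sorted(self.matched_variables),
            "unmatched_a": sorted(self.unmatched_a),
            "unmatched_b": sorted(self.unmatched_b),
            "similarity_pct": self.similarity_pct,
            "mean_jaccard_pct": self.mean_jaccard_pct,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))


def match_clusters(a: list[list[str]] | list[set[str]],
                   b: list[list[str]] | list[set[str]]) -> ClusterMatch:
    """Exhaustively match two top-k cluster lists (k <= 3).

    The assignment maximizes the total intersection size over all pairings;
    ties prefer the assignment pairing the largest clusters together
    (size-rank order), then the lexicographically smallest pairing.
    """
    A = [set(c) for c in a]
    B = [set(c) for c in b]
    if not A or not B or any(len(c) == 0 for c in A + B):
        raise ValueError("cluster lists must be non-empty")
    if len(A) > 3 or len(B) > 3:
        raise ValueError("match_clusters expects at most 3 clusters per method")

    k = min(len(A), len(B))
    size_rank_a = sorted(range(len(A)), key=lambda i: (-len(A[i]), i))
    size_rank_b = sorted(range(len(B)), key=lambda j: (-len(B[j]), j))
    size_pref = {(size_rank_a[r], size_rank_b[r]) for r in range(k)}

    best = None
    for a_idx in itertools.permutations(range(len(A)), k):
        for b_idx in itertools.permutations(range(len(B)), k):
            pairs = list(zip(a_idx, b_idx))
            total = sum(len(A[i] & B[j]) for i, j in pairs)
            n_size_pref = sum(p in size_pref for p in pairs)
            key = (-total, -n_size_pref, tuple(sorted(pairs)))
            if best is None or key < best[0]:
                best = (key, pairs)
    pairs = sorted(best[1])

    inter = [len(A[i] & B[j]) for i, j in pairs]
    union_a = set().union(*A)
    union_b = set().union(*B)
    # union of pairwise intersections over *all* cluster pairs = variables
    # covered by both methods' top-3; a variable that merely changes cluster
    # within the top-3 still counts as matched (the per-pair table shows the
    # displacement)
    matched = union_a & union_b
    universe = union_a | union_b
    jac = [100.0 * len(A[i] & B[j]) / len(A[i] | B[j]) for i, j in pairs]
    return ClusterMatch(
        clusters_a=[sorted(c) for c in A],
        clusters_b=[sorted(c) for c in B],
        assignment=pairs,
        pair_intersections=inter,
        matched_variables=matched,
        unmatched_a=union_a - matched,
        unmatched_b=union_b - matched,
        similarity_pct=round(100.0 * len(matched) / len(universe), 2),
        mean_jaccard_pct=round(float(np.mean(jac)), 2) if jac else 0.0,
    )


# --- cross-cohort phenotype tables -----------------------------------------

@dataclass
class PhenotypeTables:
    """Similar / dissimilar / unique features across the three cohorts.

    ``similar``: features in every cohort's matched set. ``dissimilar``:
    features matched in at least one AKI cohort but not in the reference
    cohort's matched set, with a status column distinguishing
    'absent_after_clustering' (present in the reference feature universe,
    dash semantics) from 'absent_before_clustering' (never in the reference
    universe, asterisk semantics). ``unique``: per cohort, features selected
    by neither method's top-3 clusters.
    """

    similar: pd.DataFrame
    dissimilar: pd.DataFrame
    unique: pd.DataFrame


def _annotate(features: list[str], metrics: dict[str, NetworkMetrics | None]
              ) -> pd.DataFrame:
    rows = []
    for f in sorted(features):
        row: dict[str, object] = {"feature": f}
        for cohort, m in metrics.items():
            if m is not None and f in m.degree.index:
                row[f"{cohort}_degree"] = float(m.degree[f])
                row[f"{cohort}_betweenness"] = round(float(m.betweenness[f]), 2)
            else:
                row[f"{cohort}_degree"] = np.nan
                row[f"{cohort}_betweenness"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def cross_cohort_similarity(matches: dict[str, ClusterMatch],
                            universes: dict[str, set[str]],
                            metrics: dict[str, NetworkMetrics | None] | None = None,
                            reference: str = "NO_AKI") -> PhenotypeTables:
    """Derive the similar/dissimilar/unique phenotype tables.

    ``matches`` maps cohort -> ClusterMatch, ``universes`` maps cohort ->
    full post-filter feature universe (features available before
    clustering).
    """
    cohorts = list(matches)
    metrics = metrics or {c: None for c in cohorts}
    matched = {c: matches[c].matched_variables for c in cohorts}
    aki = [c for c in cohorts if c != reference]

    similar_feats = sorted(set.intersection(*matched.values())) if matched else []
    similar = _annotate(similar_feats, metrics)

    dis_feats = sorted(set().union(*(matched[c] for c in aki)) - matched[reference])
    dissimilar = _annotate(dis_feats, metrics)
    if len(dissimilar):
        in_ref_universe = dissimilar["feature"].isin(universes.get(reference, set()))
        dissimilar["reference_status"] = np.where(
            in_ref_universe, "absent_after_clustering",
            "absent_before_clustering")

    uniq_rows = []
    for c in cohorts:
        selected = (set().union(*(set(x) for x in matches[c].clusters_a))
                    | set().union(*(set(x) for x in matches[c].clusters_b)))
        for f in sorted(universes.get(c, set()) - selected):
            uniq_rows.append({"cohort": c, "feature": f})
    unique = pd.DataFrame(uniq_rows, columns=["cohort", "feature"])
    if len(unique) and metrics:
        ann = _annotate(sorted(unique["feature"].unique()), metrics)
        unique = unique.merge(ann, on="feature", how="left")
    return PhenotypeTables(similar=similar, dissimilar=dissimilar, unique=unique)


# --- cohort-membership regression ------------------------------------------

def membership_regression(matrices: dict[str, FeatureMatrix],
                          predictors: list[str],
                          contrasts: tuple[tuple[str, str], ...] = (
                              ("HA_AKI", "NO_AKI"), ("CA_AKI", "NO_AKI")),
                          ) -> pd.DataFrame:
    """Logistic regression of cohort membership on selected binary features.

    One binary contrast at a time (case cohort vs reference cohort); returns
    odds ratios with Wald 95% CIs. Non-estimable coefficients (perfect
    separation / non-convergence) are flagged rather than raised.
    """
    rows = []
    for case, ref in contrasts:
        mc, mr = matrices[case], matrices[ref]
        cols = [p for p in predictors
                if p in mc.data.columns or p in mr.data.columns]
        missing = sorted(set(predictors) - set(cols))
        if missing:
            logger.warning("predictors absent from both cohorts: %s", missing)
        X = pd.concat([
            mc.data.reindex(columns=cols, fill_value=0),
            mr.data.reindex(columns=cols, fill_value=0),
        ]).to_numpy(dtype=float)
        y = np.r_[np.ones(mc.n), np.zeros(mr.n)]
        Xc = sm.add_constant(X, has_constant="add")
        try:
            fit = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
            params, bse = fit.params[1:], fit.bse[1:]
            pvals = fit.pvalues[1:]
            ok = np.isfinite(bse) & (np.abs(params) < 20)
        except Exception as exc:           # perfect separation, singular design
            logger.warning("logistic fit failed for %s vs %s: %s", case, ref, exc)
            params = bse = pvals = np.full(len(cols), np.nan)
            ok = np.zeros(len(cols), dtype=bool)
        for i, p in enumerate(cols):
            estimable = bool(ok[i])
            rows.append({
                "contrast": f"{case}_vs_{ref}", "predictor": p,
                "odds_ratio": float(np.exp(params[i])) if estimable else np.nan,
                "ci_low": float(np.exp(params[i] - 1.959963984540054 * bse[i]))
                if estimable else np.nan,
                "ci_high": float(np.exp(params[i] + 1.959963984540054 * bse[i]))
                if estimable else np.nan,
                "pvalue": float(pvals[i]) if estimable else np.nan,
                "estimable": estimable,
            })
    return pd.DataFrame(rows)
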