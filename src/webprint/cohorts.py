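"""Group-level structural-dispersion summaries over a GCD-11 matrix.

Mean (or median) pairwise GCD-11 within a set of webs is a structural
dispersion: small values mean the set shares a common topology.  The
summaries here partition a web collection by ecosystem class, source
publication, construction methodology (Ecopath flag), or decade, and compare
within-group to between-group dispersion.  No significance tests are run --
the outputs are effect sizes (absolute differences and ratios of means) --
because pairwise-distance groups with unequal dispersion and location are
poorly served by permutation ANOVA-style machinery.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .graphlets import DistanceMatrix
from .net_io import WebMetadata, metadata_frame

STATISTICS = ("mean", "median")


@dataclass
class Partition:
    """Assignment of every web to exactly one group label."""

    labels: dict[str, str]

    @property
    def web_ids(self) -> list[str]:
        return list(self.labels)

    def groups(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for wid, lab in self.labels.items():
            out.setdefault(lab, []).append(wid)
        return out


@dataclass
class CohortSummary:
    group: str
    statistic: str
    value: float
    n_webs: int
    n_pairs: int
    weight: float = 1.0


def partition_from_metadata(meta: list[WebMetadata], by: str, web_ids: list[str] | None = None) -> Partition:
    """Build a partition from metadata: by ecosystem, publication, ecopath,
    aquatic_subtype, or decade.  ``web_ids`` restricts/orders the webs."""
    frame = metadata_frame(meta)
    if web_ids is not None:
        frame = frame.loc[[w for w in web_ids if w in frame.index]]
    labels: dict[str, str] = {}
    for wid, row in frame.iterrows():
        if by == "ecosystem":
            lab = row["ecosystem"]
        elif by == "publication":
            lab = row["publication_id"]
        elif by == "ecopath":
            lab = "ecopath" if row["ecopath"] else "other"
        elif by == "aquatic_subtype":
            lab = row["aquatic_subtype"] or "none"
        elif by == "decade":
            lab = str((int(row["publication_year"]) // 10) * 10)
        else:
            raise ValueError(f"unknown partition key {by!r}")
        labels[str(wid)] = str(lab)
    return Partition(labels=labels)


def _stat(values: np.ndarray, statistic: str) -> float:
    if statistic not in STATISTICS:
        raise ValueError(f"statistic must be one of {STATISTICS}")
    return float(np.mean(values) if statistic == "mean" else np.median(values))


def _pair_values(D: DistanceMatrix, ids: list[str]) -> np.ndarray:
    idx = [D.web_ids.index(w) for w in ids]
    iu = np.array(list(combinations(range(len(idx)), 2)))
    if iu.size == 0:
        return np.array([])
    rows = np.array(idx)[iu[:, 0]]
    cols = np.array(idx)[iu[:, 1]]
    return D.values[rows, cols]


def within_group_dispersion(
    D: DistanceMatrix, group: set[str] | list[str], statistic: str = "mean", label: str = ""
) -> CohortSummary:
    """Mean/median of the C(n,2) pairwise distances inside one group.

    Groups of fewer than two webs are rejected: structural dispersion needs
    at least two webs, just as a single spring web cannot anchor a group.
    """
    ids = sorted(set(group))
    missing = [w for w in ids if w not in D.web_ids]
    if missing:
        raise KeyError(f"web ids not in distance matrix: {missing}")
    if len(ids) < 2:
        raise ValueError(f"insufficient webs in group {label or ids}: need >= 2")
    vals = _pair_values(D, ids)
    return CohortSummary(
        group=label or ",".join(ids),
        statistic=statistic,
        value=_stat(vals, statistic),
        n_webs=len(ids),
        n_pairs=len(vals),
    )


def between_group_dispersion(
    D: DistanceMatrix,
    group1: set[str] | list[str],
    group2: set[str] | list[str],
    statistic: str = "mean",
    label: str = "",
) -> CohortSummary:
    """Mean/median over all cross pairs of two disjoint groups."""
    g1, g2 = sorted(set(group1)), sorted(set(group2))
    if not g1 or not g2:
        raise ValueError("both groups must be nonempty")
    overlap = set(g1) & set(g2)
    if overlap:
        raise ValueError(f"groups overlap: {sorted(overlap)}")
    i1 = [D.web_ids.index(w) for w in g1]
    i2 = [D.web_ids.index(w) for w in g2]
    vals = D.values[np.ix_(i1, i2)].ravel()
    return CohortSummary(
        group=label or "between",
        statistic=statistic,
        value=_stat(vals, statistic),
        n_webs=len(g1) + len(g2),
        n_pairs=len(vals),
    )


def publication_weighted_mean(per_pub: list[tuple[float, int]]) -> float:
    """Average of per-publication mean distances weighted by web count."""
    if not per_pub:
        raise ValueError("no publications given")
    for value, n in per_pub:
        if n < 2:
            raise ValueError("each publication needs >= 2 webs")
    values = np.array([v for v, _ in per_pub], dtype=float)
    weights = np.array([n for _, n in per_pub], dtype=float)
    return float(np.sum(values * weights) / np.sum(weights))


def ecosystem_table(
    D: DistanceMatrix,
    meta: list[WebMetadata],
    statistic: str = "mean",
    drop_publication: str | None = None,
) -> pd.DataFrame:
    """Within/between dispersion for every pair of ecosystem classes.

    ``drop_publication`` removes one publication's webs before computing
    (the switch used to check whether a single prolific source drives a
    class's apparent coherence).
    """
    frame = metadata_frame(meta)
    if drop_publication is not None:
        frame = frame[frame["publication_id"] != drop_publication]
    frame = frame.loc[[w for w in frame.index if w in D.web_ids]]
    from .net_io import ECOSYSTEMS

    classes = list(ECOSYSTEMS)  # fixed layout: every cell always reported
    rows = []
    for i, a in enumerate(classes):
        ga = list(frame.index[frame["ecosystem"] == a])
        for b in classes[i:]:
            gb = list(frame.index[frame["ecosystem"] == b])
            degenerate = (len(ga) < 2) if a == b else (not ga or not gb)
            if degenerate:
                rows.append({"group1": a, "group2": b, "value": np.nan,
                             "n_webs": len(set(ga) | set(gb)), "n_pairs": 0,
                             "note": "insufficient webs"})
                continue
            if a == b:
                s = within_group_dispersion(D, ga, statistic, label=a)
            else:
                s = between_group_dispersion(D, ga, gb, statistic, label=f"{a}|{b}")
            rows.append({"group1": a, "group2": b, "value": s.value,
                         "n_webs": s.n_webs, "n_pairs": s.n_pairs, "note": ""})
    out = pd.DataFrame(rows)
    out.insert(0, "statistic", statistic)
    return out


def publication_table(
    D: DistanceMatrix, meta: list[WebMetadata], statistic: str = "mean"
) -> pd.DataFrame:
    """Publication-grouping summary: one-web-per-publication pooled dispersion
    vs the weighted average of per-publication dispersions, overall and split
    by era (publications up to 1999 vs after)."""
    frame = metadata_frame(meta)
    frame = frame.loc[[w for w in frame.index if w in D.web_ids]]
    counts = frame["publication_id"].value_counts()
    multi = [p for p in counts.index if counts[p] >= 2]
    single_webs = list(frame.index[frame["publication_id"].map(counts) == 1])

    rows = []
    if len(single_webs) >= 2:
        s = within_group_dispersion(D, single_webs, statistic, label="one_web_per_publication")
        rows.append({"grouping": "one_web_per_publication", "value": s.value,
                     "n_webs": s.n_webs, "n_publications": len(single_webs)})

    def weighted_rows(pubs: list[str], name: str) -> None:
        per_pub = []
        n_webs = 0
        for p in pubs:
            ids = list(frame.index[frame["publication_id"] == p])
            s = within_group_dispersion(D, ids, statistic, label=p)
            per_pub.append((s.value, s.n_webs))
            n_webs += s.n_webs
        if per_pub:
            rows.append({"grouping": name, "value": publication_weighted_mean(per_pub),
                         "n_webs": n_webs, "n_publications": len(pubs)})

    if multi:
        weighted_rows(multi, "multi_webs_per_publication")
        years = {p: int(frame.loc[frame["publication_id"] == p, "publication_year"].iloc[0]) for p in multi}
        early = [p for p in multi if years[p] <= 1999]
        late = [p for p in multi if years[p] > 1999]
        if early:
            weighted_rows(early, "multi_webs_per_publication_through_1990s")
        if late:
            weighted_rows(late, "multi_webs_per_publication_after_1990s")
    out = pd.DataFrame(rows)
    out.insert(0, "statistic", statistic)
    return out


def publication_effect(D: DistanceMatrix, partition: Partition, statistic: str = "mean") -> dict:
    """Pooled within-group vs between-group dispersion and their ratio.

    Within pools all same-label pairs over labels with >= 2 webs; between
    pools all different-label pairs.  The between/within ratio is the
    headline publication-effect statistic: values near 2 mean same-source
    webs are about twice as structurally similar as cross-source webs.
    """
    idx = {w: i for i, w in enumerate(D.web_ids)}
    within_vals, between_vals = [], []
    ids = [w for w in partition.web_ids if w in idx]
    for a, b in combinations(ids, 2):
        v = D.values[idx[a], idx[b]]
        (within_vals if partition.labels[a] == partition.labels[b] else between_vals).append(v)
    if not within_vals or not between_vals:
        raise ValueError("need both within- and between-group pairs")
    w = _stat(np.array(within_vals), statistic)
    b = _stat(np.array(between_vals), statistic)
    return {
        "within": w,
        "between": b,
        "ratio": b / w if w > 0 else np.inf,
        "n_within_pairs": len(within_vals),
        "n_between_pairs": len(between_vals),
    }


def decade_summary(
    D: DistanceMatrix, meta: list[WebMetadata], statistic: str = "mean"
) -> pd.DataFrame:
    """Dispersion by decade of publication, split by publication grouping.

    Single-network publications: plain mean/SD of all pairwise distances
    among that decade's webs.  Multi-network publications: per-publication
    dispersion aggregated with web-count weights (both the weighted SD of
    per-publication means and the weighted mean of per-publication SDs are
    reported, since either reading of a "weighted standard deviation" is
    defensible).
    """
    frame = metadata_frame(meta)
    frame = frame.loc[[w for w in frame.index if w in D.web_ids]]
    if frame["publication_year"].isna().any():
        raise ValueError("missing publication years")
    counts = frame["publication_id"].value_counts()
    frame = frame.assign(decade=(frame["publication_year"].astype(int) // 10) * 10)
    rows = []
    for decade in sorted(frame["decade"].unique()):
        sub = frame[frame["decade"] == decade]
        singles = list(sub.index[sub["publication_id"].map(counts) == 1])
        if len(singles) >= 2:
            vals = _pair_values(D, sorted(singles))
            sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else np.nan
            rows.append({"decade": int(decade), "grouping": "one_web_per_publication",
                         "value": _stat(vals, statistic), "sd": sd,
                         "mean_pub_sd": np.nan, "n_webs": len(singles),
                         "n_publications": len(singles)})
        multi = [p for p in sub["publication_id"].unique() if counts[p] >= 2]
        per_pub, sds, weights = [], [], []
        n_webs = 0
        for p in multi:
            ids = sorted(frame.index[frame["publication_id"] == p])
            vals = _pair_values(D, ids)
            per_pub.append((_stat(vals, statistic), len(ids)))
            sds.append(float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0)
            weights.append(len(ids))
            n_webs += len(ids)
        if per_pub:
            wmean = publication_weighted_mean(per_pub)
            wts = np.array(weights, dtype=float)
            means = np.array([v for v, _ in per_pub])
            wsd = float(np.sqrt(np.sum(wts * (means - wmean) ** 2) / np.sum(wts)))
            rows.append({"decade": int(decade), "grouping": "multi_webs_per_publication",
                         "value": wmean, "sd": wsd,
                         "mean_pub_sd": float(np.sum(wts * np.array(sds)) / np.sum(wts)),
                         "n_webs": n_webs, "n_publications": len(multi)})
    out = pd.DataFrame(rows)
    out.insert(0, "statistic", statistic)
    return out


def threshold_shares(
    D: DistanceMatrix, meta: list[WebMetadata], cutoffs: list[float]
) -> pd.DataFrame:
    """Share of pairwise distances at or below each cutoff, by pair category.

    Categories: same-publication pairs from multi-network publications,
    pairs among one-web-per-publication webs, and all other pairs.  Also
    reported per cutoff: among all pairs <= cutoff, the fraction that are
    same-publication; and same-publication pairs as a fraction of all pairs.
    """
    if any(c <= 0 for c in cutoffs):
        raise ValueError("cutoffs must be positive")
    frame = metadata_frame(meta)
    frame = frame.loc[[w for w in frame.index if w in D.web_ids]]
    counts = frame["publication_id"].value_counts()
    idx = {w: i for i, w in enumerate(D.web_ids)}
    same_pub, single_pairs, other = [], [], []
    for a, b in combinations(list(frame.index), 2):
        v = float(D.values[idx[a], idx[b]])
        pa, pb = frame.loc[a, "publication_id"], frame.loc[b, "publication_id"]
        if pa == pb and counts[pa] >= 2:
            same_pub.append(v)
        elif counts[pa] == 1 and counts[pb] == 1:
            single_pairs.append(v)
        else:
            other.append(v)
    all_pairs = np.array(same_pub + single_pairs + other)
    same_pub_a = np.array(same_pub)
    rows = []
    for c in cutoffs:
        below_all = int(np.sum(all_pairs <= c))
        below_same = int(np.sum(same_pub_a <= c)) if same_pub else 0
        rows.append({
            "cutoff": c,
            "share_same_publication": below_same / len(same_pub) if same_pub else np.nan,
            "share_one_web_per_publication": (np.mean(np.array(single_pairs) <= c)
                                              if single_pairs else np.nan),
            "share_other_pairs": np.mean(np.array(other) <= c) if other else np.nan,
            "frac_below_from_same_publication": below_same / below_all if below_all else np.nan,
            "same_publication_share_of_all_pairs": (len(same_pub) / len(all_pairs)
                                                    if len(all_pairs) else np.nan),
        })
    return pd.DataFrame(rows)


def mds_embed(D: DistanceMatrix, dims: int = 2) -> tuple[pd.DataFrame, float]:
    """Classical (metric) MDS of the distance matrix, for visualization.

    Eigendecomposition of the doubly-centred squared-distance matrix; axes
    are ordered by eigenvalue and sign-fixed (largest-magnitude coordinate
    positive) for determinism.  Returns coordinates and the relative stress
    sqrt(sum (d_hat - d)^2 / sum d^2).
    """
    n = len(D.web_ids)
    if dims >= n:
        raise ValueError(f"dims must be < number of webs ({n})")
    D2 = np.asarray(D.values, dtype=float) ** 2
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1][:dims]
    lam = np.clip(evals[order], 0.0, None)
    coords = evecs[:, order] * np.sqrt(lam)
    for k in range(coords.shape[1]):
        if coords[np.argmax(np.abs(coords[:, k])), k] < 0:
            coords[:, k] = -coords[:, k]
    emb = np.sqrt(np.maximum(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1), 0.0))
    denom = float((D.values ** 2).sum())
    stress = float(np.sqrt(((emb - D.values) ** 2).sum() / denom)) if denom > 0 else 0.0
    df = pd.DataFrame(coords, index=D.web_ids, columns=[f"mds{k+1}" for k in range(dims)])
    df.index.name = "web_id"
    return df, stress


def size_confound(
    D: DistanceMatrix, sizes: dict[str, int], partition: Partition, statistic: str = "mean"
) -> pd.DataFrame:
    """Diagnostics for a network-size artifact in the dispersion signal.

    Group level: Spearman rank correlation between per-group dispersion and
    (a) group mean node count, (b) group SD of node count.  Pair level: rank
    correlation of d(i,j) with |n_i - n_j| and with (n_i + n_j)/2.
    Correlations undefined on constant inputs are reported as NaN with a
    note, never as zero.
    """
    groups = {lab: ids for lab, ids in partition.groups().items() if len(ids) >= 2}
    if len(groups) < 3:
        raise ValueError("need >= 3 groups with >= 2 webs")
    disp, mean_sz, sd_sz = [], [], []
    for lab, ids in sorted(groups.items()):
        disp.append(within_group_dispersion(D, ids, statistic, label=lab).value)
        ns = np.array([sizes[w] for w in ids], dtype=float)
        mean_sz.append(float(ns.mean()))
        sd_sz.append(float(ns.std(ddof=1)))

    def rank_corr(x, y):
        x, y = np.asarray(x, float), np.asarray(y, float)
        if np.all(x == x[0]) or np.all(y == y[0]):
            return np.nan, "constant input"
        rho = spearmanr(x, y).statistic
        return float(rho), ""

    rows = []
    for name, x in (("group_mean_size", mean_sz), ("group_sd_size", sd_sz)):
        rho, note = rank_corr(x, disp)
        rows.append({"level": "group", "predictor": name, "rho": rho,
                     "n": len(disp), "note": note})

    ids = [w for w in partition.web_ids if w in D.web_ids]
    idx = {w: i for i, w in enumerate(D.web_ids)}
    dvals, absdiff, meansz = [], [], []
    for a, b in combinations(ids, 2):
        dvals.append(float(D.values[idx[a], idx[b]]))
        absdiff.append(abs(sizes[a] - sizes[b]))
        meansz.append((sizes[a] + sizes[b]) / 2)
    for name, x in (("pair_abs_size_diff", absdiff), ("pair_mean_size", meansz)):
        rho, note = rank_corr(x, dvals)
        rows.append({"level": "pair", "predictor": name, "rho": rho,
                     "n": len(dvals), "note": note})
    return pd.DataFrame(rows)
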