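"""Family-structure, demographic-prediction and network-masking analyses.

Inter-subject similarity (in latent space or in observed edge space) is
grouped by relationship (unrelated / sibling / DZ twin / MZ twin /
self-retest), z-scored against the unrelated distribution, and group
separability is quantified by the Mann-Whitney AUC, with matched
permutation tests comparing latent vs observed separability. Demographic
models (linear SVC for sex; linear-kernel ridge for age and cognition) are
fitted with family-blocked cross-validation so siblings never span folds.
The network-masking sensitivity analysis replaces every edge not touching a
chosen functional network with the training population mean and re-scores
the pipeline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.kernel_ridge import KernelRidge
from sklearn.metrics import balanced_accuracy_score, mean_absolute_error
from sklearn.model_selection import GridSearchCV, GroupKFold
from sklearn.svm import LinearSVC
from statsmodels.stats.multitest import multipletests

from .flavors import CohortTable, EdgeVectorSet, ValidationError, edge_index

__all__ = [
    "RelationshipPairs", "NetworkAssignment", "relationship_pairs_from_cohort",
    "match_unrelated_pairs", "similarity_by_relationship",
    "zscore_by_unrelated", "roc_separability",
    "permutation_compare_separability", "fdr_correct",
    "fit_demographic_models", "bootstrap_performance",
    "mask_to_network", "sensitivity_sweep",
]

RELATIONS = ("unrelated", "sibling", "DZ", "MZ", "self-retest")


@dataclass
class RelationshipPairs:
    """Unordered, unique subject pairs with relationship labels."""

    table: pd.DataFrame  # columns: subject_a, subject_b, relation, age_diff, sex_match

    def __post_init__(self):
        need = {"subject_a", "subject_b", "relation"}
        if not need.issubset(self.table.columns):
            raise ValidationError(f"pair table needs columns {sorted(need)}")
        bad = set(self.table["relation"]) - set(RELATIONS)
        if bad:
            raise ValidationError(f"unknown relation labels: {sorted(bad)}")
        key = self.table.apply(
            lambda r: tuple(sorted((r["subject_a"], r["subject_b"]))), axis=1)
        if key.duplicated().any():
            raise ValidationError("duplicate pairs")

    def of(self, relation: str) -> pd.DataFrame:
        return self.table[self.table["relation"] == relation]


@dataclass
class NetworkAssignment:
    """Region index -> network label (every region exactly one network)."""

    labels: list[str]

    @property
    def networks(self) -> list[str]:
        return sorted(set(self.labels))

    def regions_of(self, network: str) -> np.ndarray:
        if network not in self.labels:
            raise ValidationError(f"unknown network {network!r}")
        return np.array([i for i, l in enumerate(self.labels) if l == network])


def relationship_pairs_from_cohort(cohort: CohortTable,
                                   split: str | None = None) -> RelationshipPairs:
    """Derive MZ/DZ/sibling/self-retest pairs from a cohort table."""
    t = cohort.table
    if split is not None:
        t = t[t["split"] == split]
    rows = []
    base = t[t["retest_of"].isna() | (t["retest_of"] == "")]
    for fam, grp in base.groupby("family_id"):
        if pd.isna(fam) or fam == "" or len(grp) < 2:
            continue
        members = grp["subject_id"].tolist()
        zyg = grp["zygosity"].iloc[0]
        rel = {"MZ": "MZ", "DZ": "DZ", "sibling": "sibling"}.get(zyg)
        if rel is None:
            continue
        ages = dict(zip(grp["subject_id"], grp["age"]))
        sexes = dict(zip(grp["subject_id"], grp["sex"]))
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                a, b = members[i], members[j]
                rows.append(dict(subject_a=a, subject_b=b, relation=rel,
                                 age_diff=abs(ages[a] - ages[b]),
                                 sex_match=sexes[a] == sexes[b]))
    rt = t[(t["retest_of"].notna()) & (t["retest_of"] != "")]
    for _, r in rt.iterrows():
        rows.append(dict(subject_a=r["retest_of"], subject_b=r["subject_id"],
                         relation="self-retest", age_diff=0.0, sex_match=True))
    return RelationshipPairs(pd.DataFrame(
        rows, columns=["subject_a", "subject_b", "relation", "age_diff",
                       "sex_match"]))


def match_unrelated_pairs(cohort: CohortTable, target_pairs: RelationshipPairs,
                          split: str | None = None,
                          seed: int = 0) -> RelationshipPairs:
    """Unrelated pairs matched to each related pair on sex pairing and age gap.

    For every related pair, picks the unrelated (different-family) pair with
    the same sex pairing and the closest age difference, avoiding reuse of
    an identical pair when alternatives exist. Pairs with no candidate are
    dropped with a warning.
    """
    t = cohort.table
    if split is not None:
        t = t[t["split"] == split]
    t = t[t["retest_of"].isna() | (t["retest_of"] == "")]
    ids = t["subject_id"].tolist()
    age = dict(zip(t["subject_id"], t["age"]))
    sex = dict(zip(t["subject_id"], t["sex"]))
    fam = dict(zip(t["subject_id"], t["family_id"]))
    candidates = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            a, b = ids[i], ids[j]
            if fam[a] == fam[b] and fam[a] not in ("", None):
                continue
            candidates.append((a, b, abs(age[a] - age[b]), sex[a] == sex[b]))
    used: set = set()
    rows = []
    for _, r in target_pairs.table.iterrows():
        if r["relation"] == "unrelated":
            continue
        best, best_gap = None, np.inf
        for a, b, ad_, sm in candidates:
            if sm != r["sex_match"] or (a, b) in used:
                continue
            gap = abs(ad_ - r["age_diff"])
            if gap < best_gap:
                best, best_gap = (a, b, ad_, sm), gap
        if best is None:
            # allow reuse before giving up
            for a, b, ad_, sm in candidates:
                if sm != r["sex_match"]:
                    continue
                gap = abs(ad_ - r["age_diff"])
                if gap < best_gap:
                    best, best_gap = (a, b, ad_, sm), gap
        if best is None:
            warnings.warn(f"no unrelated match for pair "
                          f"({r['subject_a']},{r['subject_b']}): dropped")
            continue
        used.add(best[:2])
        rows.append(dict(subject_a=best[0], subject_b=best[1],
                         relation="unrelated", age_diff=best[2],
                         sex_match=best[3]))
    df = pd.DataFrame(rows, columns=["subject_a", "subject_b", "relation",
                                     "age_diff", "sex_match"])
    df = df.drop_duplicates(subset=["subject_a", "subject_b"])
    return RelationshipPairs(df)


def similarity_by_relationship(sim: np.ndarray, subject_ids: list[str],
                               pairs: RelationshipPairs) -> dict[str, np.ndarray]:
    """Group pairwise similarities by relationship label."""
    S = np.asarray(sim, dtype=float)
    if S.shape[0] != S.shape[1] or np.max(np.abs(S - S.T)) > 1e-8:
        raise ValidationError("similarity matrix must be square symmetric")
    pos = {s: i for i, s in enumerate(subject_ids)}
    out: dict[str, list] = {rel: [] for rel in RELATIONS}
    for _, r in pairs.table.iterrows():
        a, b = r["subject_a"], r["subject_b"]
        if a not in pos or b not in pos:
            raise ValidationError(f"pair ({a},{b}) outside the similarity matrix")
        out[r["relation"]].append(S[pos[a], pos[b]])
    return {rel: np.array(v) for rel, v in out.items()}


def zscore_by_unrelated(groups: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    """Z-score every group by the unrelated group's mean and sd."""
    un = np.asarray(groups.get("unrelated", []), dtype=float)
    if un.size < 2:
        raise ValidationError("unrelated group needs >= 2 values")
    sd = un.std(ddof=0)
    if sd == 0:
        raise ValidationError("unrelated similarities have zero variance")
    mu = un.mean()
    return {rel: (np.asarray(v, dtype=float) - mu) / sd
            for rel, v in groups.items()}


def roc_separability(group_a: np.ndarray, group_b: np.ndarray) -> float:
    """Mann-Whitney AUC: P(b > a) with ties counting 1/2."""
    a = np.asarray(group_a, dtype=float).ravel()
    b = np.asarray(group_b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValidationError("both groups must be nonempty")
    u = stats.mannwhitneyu(b, a, alternative="two-sided").statistic
    return float(u / (a.size * b.size))


def permutation_compare_separability(latent_a, latent_b, observed_a, observed_b,
                                     n_perm: int = 10000, seed: int = 0,
                                     exact: bool = False) -> dict:
    """Two-sided matched permutation test of AUC(latent) - AUC(observed).

    The same pairs are scored in both spaces; under the null, which space a
    pair's score came from is exchangeable, so each permutation swaps the
    latent/observed scores of a random subset of matched pairs (group-a and
    group-b lists are matched elementwise across spaces). With ``exact``,
    all 2^(n_a + n_b) swap patterns are enumerated (small inputs only).
    """
    la = np.asarray(latent_a, dtype=float)
    lb = np.asarray(latent_b, dtype=float)
    oa = np.asarray(observed_a, dtype=float)
    ob = np.asarray(observed_b, dtype=float)
    if la.shape != oa.shape or lb.shape != ob.shape:
        raise ValidationError("latent/observed score lists are not matched")
    if n_perm < 1 and not exact:
        raise ValidationError("n_perm must be >= 1")
    stat = roc_separability(la, lb) - roc_separability(oa, ob)

    def swapped(mask_a, mask_b):
        la2 = np.where(mask_a, oa, la)
        oa2 = np.where(mask_a, la, oa)
        lb2 = np.where(mask_b, ob, lb)
        ob2 = np.where(mask_b, lb, ob)
        return roc_separability(la2, lb2) - roc_separability(oa2, ob2)

    if exact:
        na, nb = la.size, lb.size
        if na + nb > 20:
            raise ValidationError("exact enumeration limited to <= 20 pairs")
        count, total = 0, 0
        for code in range(2 ** (na + nb)):
            mask_a = np.array([(code >> k) & 1 for k in range(na)], dtype=bool)
            mask_b = np.array([(code >> (na + k)) & 1 for k in range(nb)], dtype=bool)
            if abs(swapped(mask_a, mask_b)) >= abs(stat) - 1e-12:
                count += 1
            total += 1
        return {"statistic": stat, "p_value": count / total, "n_perm": total}

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        mask_a = rng.random(la.size) < 0.5
        mask_b = rng.random(lb.size) < 0.5
        if abs(swapped(mask_a, mask_b)) >= abs(stat) - 1e-12:
            count += 1
    return {"statistic": stat, "p_value": (count + 1) / (n_perm + 1),
            "n_perm": n_perm}


def fdr_correct(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float).ravel()
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# demographic prediction


_DEFAULT_GRID = np.logspace(-4, 4, 9)


def fit_demographic_models(features: np.ndarray, targets: pd.DataFrame,
                           groups: np.ndarray, train_idx: np.ndarray,
                           test_idx: np.ndarray, seed: int = 0,
                           inner_folds: int = 3) -> dict:
    """Sex / age / cognition prediction with nested family-blocked CV.

    ``features`` is n_subj x p (latent vectors, or rows of an averaged
    inter-subject similarity matrix restricted to training-subject columns
    upstream). ``targets`` columns: ``sex`` (labels) and any numeric
    columns (age, cognition composites). Hyperparameters are chosen by an
    inner GroupKFold grid search on the training subjects only; scores are
    computed on the held-out test subjects.

    Returns ``{"sex": {...}, "<numeric>": {...}, "predictions": {...}}``.
    """
    X = np.asarray(features, dtype=float)
    groups = np.asarray(groups)
    results: dict = {"predictions": {}}
    Xtr, Xte = X[train_idx], X[test_idx]
    gtr = groups[train_idx]
    n_groups = len(set(gtr))
    cv = GroupKFold(n_splits=min(inner_folds, n_groups))

    if "sex" in targets.columns:
        y = targets["sex"].to_numpy()
        ytr, yte = y[train_idx], y[test_idx]
        if len(set(ytr)) < 2:
            warnings.warn("single class in training subjects: sex model skipped")
            results["sex"] = {"balanced_accuracy": np.nan}
        else:
            gs = GridSearchCV(LinearSVC(), {"C": _DEFAULT_GRID}, cv=cv,
                              scoring="balanced_accuracy")
            gs.fit(Xtr, ytr, groups=gtr)
            pred = gs.predict(Xte)
            results["sex"] = {
                "balanced_accuracy": float(balanced_accuracy_score(yte, pred)),
                "C": float(gs.best_params_["C"]),
            }
            results["predictions"]["sex"] = pred

    for col in targets.columns:
        if col == "sex":
            continue
        y = targets[col].to_numpy(dtype=float)
        ytr, yte = y[train_idx], y[test_idx]
        if np.ptp(ytr) < 1e-14:
            warnings.warn(f"constant target {col!r}: model degenerate")
            results[col] = {"r": np.nan, "mae": np.nan}
            continue
        gs = GridSearchCV(KernelRidge(kernel="linear"),
                          {"alpha": _DEFAULT_GRID}, cv=cv,
                          scoring="neg_mean_absolute_error")
        gs.fit(Xtr, ytr, groups=gtr)
        pred = gs.predict(Xte)
        if np.ptp(pred) < 1e-14:
            r = 0.0
        else:
            r = float(stats.pearsonr(yte, pred).statistic)
        results[col] = {"r": r,
                        "mae": float(mean_absolute_error(yte, pred)),
                        "alpha": float(gs.best_params_["alpha"])}
        results["predictions"][col] = pred
    return results


def bootstrap_performance(y_true: np.ndarray, y_pred: np.ndarray,
                          score_fn, n_boot: int = 100,
                          seed: int = 0) -> dict:
    """Bootstrap (resampling subjects with replacement) a score function.

    Returns the mean plus central 50% and 90% intervals; fully seeded.
    """
    if n_boot < 2:
        raise ValidationError("n_boot must be >= 2")
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    rng = np.random.default_rng(seed)
    n = y_true.shape[0]
    scores = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        scores[b] = score_fn(y_true[idx], y_pred[idx])
    return {
        "mean": float(scores.mean()),
        "interval50": (float(np.percentile(scores, 25)),
                       float(np.percentile(scores, 75))),
        "interval90": (float(np.percentile(scores, 5)),
                       float(np.percentile(scores, 95))),
        "scores": scores,
    }


# ---------------------------------------------------------------------------
# network masking


def mask_to_network(x: EdgeVectorSet, assignment: NetworkAssignment,
                    network: str, mu_train: np.ndarray) -> EdgeVectorSet:
    """Keep only the edges touching a network; replace the rest with mu_train.

    An edge survives if either endpoint region belongs to the network;
    edges between two non-network regions are set to the training-population
    mean value of that edge.
    """
    n_regions = x.flavor.n_regions
    if len(assignment.labels) != n_regions:
        raise ValidationError("network assignment does not cover the atlas")
    mu = np.asarray(mu_train, dtype=float).ravel()
    if mu.size != x.data.shape[1]:
        raise ValidationError("mu_train length mismatch")
    in_net = np.zeros(n_regions, dtype=bool)
    if isinstance(network, str):
        in_net[assignment.regions_of(network)] = True
    else:  # explicit region index collection (may be empty)
        in_net[np.asarray(list(network), dtype=int)] = True
    keep = np.array([in_net[i] or in_net[j] for i, j in edge_index(n_regions)])
    data = np.where(keep, x.data, mu)
    return EdgeVectorSet(x.flavor, list(x.subject_ids), data)


def _mask_all_flavors(edge_sets, assignment, network, model):
    out = {}
    for name, es in edge_sets.items():
        mu = model.reductions[name].train_mean
        out[name] = (mask_to_network(es, assignment, network, mu)
                     if network is not None else es)
    return out


def sensitivity_sweep(model, train_edges: dict, test_edges: dict,
                      assignment: NetworkAssignment,
                      demo_targets: pd.DataFrame | None = None,
                      demo_groups: np.ndarray | None = None,
                      fusion_rule: str = "fusion", seed: int = 0) -> pd.DataFrame:
    """Per-network masking report (plus a non-masked reference row).

    For each network: mask all input flavors, recompute fusion latents,
    score fusion connectome predictions (mean avgrank / avgcorr_demean over
    target flavors) and, if demographic targets are given, re-fit the
    demographic predictors on masked training features.
    """
    from .metrics import avgcorr_demean as _acd, avgrank as _ar
    from .model import decode as _decode, fuse as _fuse, fusion_subset
    from .reduction import reduce as _reduce, restore as _restore

    rows = []
    networks = [None] + assignment.networks
    names = [f.name for f in model.flavors]
    for network in networks:
        masked_test = _mask_all_flavors(test_edges, assignment, network, model)
        include = fusion_subset(model, fusion_rule)
        latents = [model.encode_edges(masked_test[n], n) for n in include]
        fused = _fuse(latents, label=fusion_rule)
        ranks, acds = [], []
        for tgt in names:
            pred = _restore(_decode(fused.data, model.codecs[tgt]),
                            model.reductions[tgt])
            meas = test_edges[tgt].data
            mu = model.reductions[tgt].train_mean
            ranks.append(_ar(meas, pred))
            acds.append(_acd(meas, pred, mu))
        row = {"network": network if network is not None else "non-masked",
               "avgrank": float(np.mean(ranks)),
               "avgcorr_demean": float(np.mean(acds))}
        if demo_targets is not None:
            masked_train = _mask_all_flavors(train_edges, assignment, network, model)
            ltr = _fuse([model.encode_edges(masked_train[n], n) for n in include],
                        label=fusion_rule)
            lte = fused
            Xall = np.vstack([ltr.data, lte.data])
            n_tr = ltr.data.shape[0]
            idx_tr = np.arange(n_tr)
            idx_te = np.arange(n_tr, Xall.shape[0])
            res = fit_demographic_models(Xall, demo_targets, demo_groups,
                                         idx_tr, idx_te, seed=seed)
            for key, val in res.items():
                if key == "predictions":
                    continue
                for m, v in val.items():
                    if m in ("balanced_accuracy", "r", "mae"):
                        row[f"{key}_{m}"] = v
        rows.append(row)
    return pd.DataFrame(rows)
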