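"""Additive per-transcript feature attributions and factor-level scores.

For tree ensembles the attributions are TreeSHAP values (exact Shapley
values under the tree path-dependent feature perturbation), computed by the
boosters themselves; random forests use path (Saabas) attributions, which
share the additivity property; ridge models use coefficient * (x - x_bar).
In every route the invariant

    base_value + sum_j phi[i, j] == prediction_i

holds per transcript, and all downstream scores are derived from it: a
factor's score S_f is the sum over the factor's columns of the mean
absolute per-transcript attribution, its share s_f = S_f / sum_f S_f. The
minimal influential factor set is the shortest share-sorted prefix reaching
a target cumulative share (default 50%).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .modeling import PausingRegressor


@dataclass
class ContributionTable:
    """Signed per-transcript per-feature attributions plus the base value."""

    phi: pd.DataFrame  # transcripts x features
    base_value: float
    predictions: pd.Series

    def check_additivity(self, rtol: float = 1e-4) -> None:
        recon = self.base_value + self.phi.sum(axis=1)
        scale = np.maximum(np.abs(self.predictions.to_numpy()), 1.0)
        err = np.abs(recon.to_numpy() - self.predictions.to_numpy()) / scale
        if err.max() > rtol:
            raise AssertionError(
                f"attribution additivity violated: max rel err {err.max():.2e}"
            )

    def mean_abs(self) -> pd.Series:
        """Per-feature mean absolute attribution (importance)."""
        return self.phi.abs().mean(axis=0)


def _rf_path_attributions(
    model, X: np.ndarray
) -> Tuple[np.ndarray, float]:
    """Saabas path attributions for a sklearn forest: along each sample's
    root-to-leaf path, the change in node mean at every split is credited to
    the split feature. Additive by construction."""
    n, p = X.shape
    phi = np.zeros((n, p))
    base = 0.0
    for est in model.estimators_:
        tree = est.tree_
        values = tree.value.reshape(-1)
        path = est.decision_path(X)  # CSR samples x nodes
        dense = np.asarray(path.todense(), dtype=float)
        base += values[0]
        for node in range(tree.node_count):
            lc, rc = tree.children_left[node], tree.children_right[node]
            if lc == -1:
                continue
            f = tree.feature[node]
            phi[:, f] += dense[:, lc] * (values[lc] - values[node])
            phi[:, f] += dense[:, rc] * (values[rc] - values[node])
    k = len(model.estimators_)
    return phi / k, base / k


def compute_attributions(
    model: PausingRegressor, X: pd.DataFrame
) -> ContributionTable:
    """Per-transcript additive attributions for a fitted PausingRegressor."""
    Xa = X[list(model.feature_names_in_)]
    Xv = Xa.to_numpy(dtype=np.float32)
    if model.learner == "xgb":
        import xgboost as xgb

        contrib = model.model_.predict(xgb.DMatrix(Xv), pred_contribs=True)
        phi, base = contrib[:, :-1], float(contrib[0, -1])
    elif model.learner == "gbdt":
        contrib = model.model_.predict(Xv, pred_contrib=True)
        phi, base = contrib[:, :-1], float(contrib[0, -1])
    elif model.learner == "rf":
        phi, base = _rf_path_attributions(model.model_, Xv.astype(np.float64))
    elif model.learner == "ridge":
        coef = model.model_.coef_
        centered = Xa.to_numpy(dtype=float) - model.train_mean_
        phi = centered * coef
        base = float(model.model_.intercept_ + coef @ model.train_mean_)
    else:  # pragma: no cover
        raise ValueError(f"no attribution route for learner {model.learner!r}")
    preds = pd.Series(model.predict(Xa), index=Xa.index, dtype=float)
    table = ContributionTable(
        phi=pd.DataFrame(phi, index=Xa.index, columns=Xa.columns),
        base_value=base,
        predictions=preds,
    )
    table.check_additivity()
    return table


def _column_factor_map(
    columns: Sequence[str], metadata: pd.DataFrame
) -> Dict[str, str]:
    meta = metadata.set_index("name")
    out = {}
    for c in columns:
        if c not in meta.index:
            raise ValueError(f"column {c!r} missing from metadata")
        row = meta.loc[c]
        out[c] = row["factor"] if row["kind"] == "binding" else "annotation"
    return out


def aggregate_by_factor(
    ct: ContributionTable,
    metadata: pd.DataFrame,
    share_base: str = "factors",
) -> pd.DataFrame:
    """Aggregate attributions to one score and share per factor.

    S_f sums mean |phi| over the factor's columns (annotation columns pool
    into the pseudo-factor ``annotation``). ``share_base`` selects the share
    denominator: ``"factors"`` (annotation excluded, the default reading of
    factor rankings) or ``"all"``.
    """
    if share_base not in ("factors", "all"):
        raise ValueError("share_base must be 'factors' or 'all'")
    importance = ct.mean_abs()
    cmap = _column_factor_map(list(importance.index), metadata)
    s = importance.groupby(importance.index.map(cmap)).sum()
    df = pd.DataFrame({"S": s}).sort_values("S", ascending=False)
    base = df["S"].drop(index="annotation", errors="ignore") if share_base == "factors" else df["S"]
    total = float(base.sum())
    df["share"] = (df["S"] / total if total > 0 else 0.0)
    if share_base == "factors" and "annotation" in df.index:
        df.loc["annotation", "share"] = np.nan
    df.index.name = "factor"
    return df


def aggregate_by_group(
    scores: pd.Series, grouping: Mapping[str, Iterable[str]]
) -> pd.Series:
    """Sum member scores per group; members in several groups count in each;
    absent members contribute 0 (so empty groups score 0)."""
    out = {}
    for name, members in grouping.items():
        out[name] = float(sum(scores.get(m, 0.0) for m in members))
    return pd.Series(out)


def binding_mode(name: str, metadata: pd.DataFrame) -> Optional[str]:
    """Binding mode of a column: DNA/RNA x region, ncRNA-proximal pooled."""
    row = metadata.set_index("name").loc[name]
    if row["kind"] != "binding":
        return None
    mode = "DNA" if row["assay"] == "chip" else "RNA"
    if pd.notna(row["rank"]):
        return f"{mode}_ncRNA"
    return f"{mode}_{row['region']}"


def aggregate_by_binding_mode(
    ct: ContributionTable, metadata: pd.DataFrame
) -> pd.Series:
    """Aggregate |phi| importance over binding modes (assay x region)."""
    importance = ct.mean_abs()
    meta = metadata.set_index("name")
    modes: Dict[str, float] = {}
    for c, v in importance.items():
        row = meta.loc[c]
        if row["kind"] != "binding":
            continue
        mode = "DNA" if row["assay"] == "chip" else "RNA"
        key = f"{mode}_ncRNA" if pd.notna(row["rank"]) else f"{mode}_{row['region']}"
        modes[key] = modes.get(key, 0.0) + float(v)
    return pd.Series(modes).sort_values(ascending=False)


def factor_mode_scores(
    ct: ContributionTable, metadata: pd.DataFrame
) -> pd.DataFrame:
    """Factors x binding modes table of summed mean-|phi| importances."""
    importance = ct.mean_abs()
    meta = metadata.set_index("name")
    rows: Dict[Tuple[str, str], float] = {}
    for c, v in importance.items():
        row = meta.loc[c]
        if row["kind"] != "binding":
            continue
        mode = "DNA" if row["assay"] == "chip" else "RNA"
        key = f"{mode}_ncRNA" if pd.notna(row["rank"]) else f"{mode}_{row['region']}"
        rows[(row["factor"], key)] = rows.get((row["factor"], key), 0.0) + float(v)
    ser = pd.Series(rows)
    return ser.unstack(fill_value=0.0)


def select_minimal_factor_set(
    shares: pd.Series, target_share: float = 0.5
) -> List[str]:
    """Shortest prefix of share-sorted factors reaching the target share.

    Sorting is by descending share with lexicographic tie-break; the prefix
    is minimal: dropping its last member falls below the target.
    """
    if not (0.0 < target_share <= 1.0):
        raise ValueError("target_share must be in (0, 1]")
    shares = shares.dropna()
    order = sorted(shares.index, key=lambda f: (-shares[f], f))
    cum = 0.0
    picked: List[str] = []
    for f in order:
        picked.append(f)
        cum += float(shares[f])
        if cum >= target_share - 1e-12:
            break
    else:
        raise ValueError("shares sum below target; cannot reach it")
    if len(picked) > 1:
        assert cum - float(shares[picked[-1]]) < target_share
    return picked


def fisher_enrichment(
    table: Sequence[Sequence[int]] | np.ndarray, alternative: str = "greater"
) -> Tuple[float, float]:
    """One-sided Fisher exact test on a 2x2 count table.

    Returns ``(odds_ratio, p)`` with the sample odds ratio ad/bc (``inf``
    when bc = 0 and ad > 0, ``nan`` when both products vanish) and the
    conditional hypergeometric p-value for the stated alternative.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        if np.any(t != np.floor(t)) or np.any(t < 0):
            raise ValueError("counts must be non-negative integers")
        t = t.astype(int)
    a, b, c, d = t[0, 0], t[0, 1], t[1, 0], t[1, 1]
    if b * c == 0:
        orat = float("inf") if a * d > 0 else float("nan")
    else:
        orat = float(a * d) / float(b * c)
    _, p = stats.fisher_exact(t, alternative=alternative)
    return orat, float(p)


def splicing_intron_enrichment_table(
    rna_intron_scores: pd.Series, splicing_members: Iterable[str]
) -> np.ndarray:
    """2x2 table: top RNA-intron contributors (above across-factor median)
    vs membership in the splicing factor set."""
    members = set(splicing_members)
    median = float(rna_intron_scores.median())
    top = rna_intron_scores > median
    in_set = rna_intron_scores.index.isin(members)
    a = int((top & in_set).sum())
    b = int((top & ~in_set).sum())
    c = int((~top & in_set).sum())
    d = int((~top & ~in_set).sum())
    return np.array([[a, b], [c, d]])
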