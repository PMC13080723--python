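"""Reference state profiles, signature weight vectors, rank-sum marker genes.

The signature construction is the core of the scoring method: from a labeled
CD8 reference (naive / effector / memory), per-state mean log-normalized
profiles give two per-gene weight vectors,

    w_eff = mean(effector) - mean(naive)     (naive -> effector transition)
    w_mem = mean(memory)  - mean(effector)   (effector -> memory transition)

which downstream are dotted with a sample's delta-expression vector. The
module also implements the two-group Wilcoxon rank-sum marker screen
(normal approximation with tie correction, signed z, BH adjustment) and the
fold-change + top-k selection rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ReferenceExpression, ValidationError, REQUIRED_STATES

LOG_NORM_TARGET = 1e4
FC_EPSILON = 1e-9


@dataclass
class StateProfiles:
    """Per-state mean expression profiles over the labeled reference cells."""

    means: pd.DataFrame  # genes x states (naive, effector, memory)
    n_cells: dict[str, int]


@dataclass
class SignatureVectors:
    """Per-gene effector and memory transition weights on a shared universe."""

    weights: pd.DataFrame  # index gene_id; columns w_eff, w_mem

    @property
    def gene_ids(self) -> pd.Index:
        return self.weights.index

    @property
    def w_eff(self) -> pd.Series:
        return self.weights["w_eff"]

    @property
    def w_mem(self) -> pd.Series:
        return self.weights["w_mem"]


def log_normalize_reference(
    ref: ReferenceExpression, target: float = LOG_NORM_TARGET
) -> ReferenceExpression:
    """Per cell: value <- log2(value / cell_sum * target + 1).

    Identity when the reference is already tagged log_normalized.
    """
    if ref.value_scale == "log_normalized":
        return ref
    colsums = ref.values.sum(axis=0)
    if (colsums == 0).any():
        bad = colsums.index[colsums == 0][0]
        raise ValidationError(f"cell {bad!r} has zero total counts")
    values = np.log2(ref.values.div(colsums, axis=1) * target + 1.0)
    return ReferenceExpression(values, ref.cell_state, "log_normalized")


def state_mean_profiles(ref: ReferenceExpression) -> StateProfiles:
    """Arithmetic mean profile per required state; other labels excluded."""
    if ref.value_scale != "log_normalized":
        raise ValidationError("state profiles require log-normalized values")
    means = {}
    n_cells = {}
    for state in REQUIRED_STATES:
        cells = ref.cell_state.index[ref.cell_state == state]
        if len(cells) == 0:
            raise ValidationError(f"no cells labeled {state!r} in reference")
        means[state] = ref.values[cells].mean(axis=1)
        n_cells[state] = len(cells)
    return StateProfiles(pd.DataFrame(means), n_cells)


def build_signatures(
    profiles: StateProfiles, universe: list[str] | None = None
) -> SignatureVectors:
    """w_eff = effector - naive; w_mem = memory - effector, per gene."""
    m = profiles.means
    if universe is not None:
        missing = [g for g in universe if g not in m.index]
        if missing:
            raise ValidationError(
                f"universe genes absent from profiles: {missing[:5]}"
            )
        m = m.loc[universe]
    weights = pd.DataFrame(
        {
            "w_eff": m["effector"] - m["naive"],
            "w_mem": m["memory"] - m["effector"],
        }
    )
    weights.index.name = "gene_id"
    return SignatureVectors(weights)


def _ranksum_z(values: np.ndarray, n_a: int) -> np.ndarray:
    """Signed rank-sum z per row; columns [0, n_a) are group A.

    Normal approximation with tie correction; positive z means higher in A.
    Rows where every value ties give z = 0.
    """
    n = values.shape[1]
    n_b = n - n_a
    ranks = stats.rankdata(values, axis=1)
    r_a = ranks[:, :n_a].sum(axis=1)
    u = r_a - n_a * (n_a + 1) / 2.0
    mu = n_a * n_b / 2.0
    tie_term = np.empty(len(values))
    for i, row in enumerate(values):
        _, cnt = np.unique(row, return_counts=True)
        tie_term[i] = np.sum(cnt**3 - cnt)
    var = n_a * n_b / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    z = np.zeros(len(values))
    ok = var > 0
    z[ok] = (u[ok] - mu) / np.sqrt(var[ok])
    return z


def wilcoxon_deg(
    ref: ReferenceExpression, group_a, group_b
) -> pd.DataFrame:
    """Two-sided rank-sum test per gene between two cell groups.

    Returns a table indexed by gene with columns statistic (signed z,
    positive = higher in group_a), p_value, adjusted_p (BH), log2_fc
    (on de-logged means with pseudocount), mean_a, mean_b.
    """
    if ref.value_scale != "log_normalized":
        raise ValidationError("wilcoxon_deg requires log-normalized values")
    group_a, group_b = list(group_a), list(group_b)
    if not group_a or not group_b:
        raise ValidationError("both groups must be non-empty")
    if set(group_a) & set(group_b):
        raise ValidationError("groups overlap")
    a = ref.values[group_a].to_numpy()
    b = ref.values[group_b].to_numpy()
    z = _ranksum_z(np.hstack([a, b]), n_a=a.shape[1])
    p = 2.0 * stats.norm.sf(np.abs(z))
    adj = multipletests(p, method="fdr_bh")[1]
    # fold change on the de-logged scale: expm(x) = 2^x - 1
    ma = (2.0 ** a - 1.0).mean(axis=1)
    mb = (2.0 ** b - 1.0).mean(axis=1)
    log2_fc = np.log2((ma + FC_EPSILON) / (mb + FC_EPSILON))
    return pd.DataFrame(
        {
            "statistic": z,
            "p_value": p,
            "adjusted_p": adj,
            "log2_fc": log2_fc,
            "mean_a": ma,
            "mean_b": mb,
        },
        index=ref.values.index.rename("gene_id"),
    )


def select_genes(
    deg: pd.DataFrame,
    fc_min: float = 2.0,
    top_n: int = 100,
    rank_by: str = "statistic",
) -> list[str]:
    """Filter |fold change| >= fc_min, then take the top_n ranked genes.

    ``rank_by='statistic'`` orders by |z| descending, ``'adjusted_p'`` by
    adjusted p ascending; ties break deterministically by gene id. May
    return fewer than top_n genes.
    """
    if deg.empty:
        raise ValidationError("empty DEG table")
    survivors = deg[deg["log2_fc"].abs() >= np.log2(fc_min)]
    if rank_by == "statistic":
        key = -survivors["statistic"].abs()
    elif rank_by == "adjusted_p":
        key = survivors["adjusted_p"]
    else:
        raise ValidationError(f"unknown rank_by {rank_by!r}")
    order = pd.DataFrame({"key": key, "gene": survivors.index}).sort_values(
        ["key", "gene"], kind="stable"
    )
    return order["gene"].head(top_n).tolist()


def overlap_lists(
    list_a, list_b_up, list_b_down
) -> tuple[int, int, list[str]]:
    """Directional overlap bookkeeping between a gene list and an up/down split.

    Returns (#A∩up, #A∩down, sorted members of both intersections).
    """
    sa = set(list_a)
    up = sa & set(list_b_up)
    down = sa & set(list_b_down)
    return len(up), len(down), sorted(up | down)
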