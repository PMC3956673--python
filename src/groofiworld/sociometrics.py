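"""Sociometric statistics: dominance indices, interaction matrices, TauKr
matrix permutation correlations, rank-sum tests, and cross-run probability
combination.

The average dominance index (ADI) of an individual is the mean, over the
dyads in which it fought at least once, of the proportion of those dyadic
fights it won; ranks order individuals by descending ADI.  TauKr measures
row-wise association between two actor x receiver matrices: the mean over
actors of Kendall's tau-b between their rows (diagonal excluded), with
significance from jointly permuting the row and column identities of one
matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import EVENT_FIGHT, EVENT_GROOM, EventLog
from .pcmc import PCMCResult, analyze_log


# --------------------------------------------------------------------------
# Dominance
# --------------------------------------------------------------------------

def build_wins_matrix(log: EventLog, n_ids: int | None = None) -> np.ndarray:
    """Square matrix of collection-window fight wins, cell (i, j) = fights
    won by i against j."""
    if n_ids is None:
        n_ids = int(log.actor.max()) + 1
    rows = np.flatnonzero((log.event == EVENT_FIGHT) & log.collected)
    wins = np.zeros((n_ids, n_ids), dtype=np.int64)
    for r in rows:
        w = int(log.winner[r])
        loser = int(log.victim[r]) if w == log.aggressor[r] else int(log.aggressor[r])
        wins[w, loser] += 1
    return wins


def average_dominance_index(wins: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(ADI, ranks): ADI_i = mean over fought dyads of wins_ij/(wins_ij+wins_ji);
    NaN for individuals with no fights, ranked last; ties break to lower id."""
    wins = np.asarray(wins, dtype=float)
    total = wins + wins.T
    with np.errstate(invalid="ignore", divide="ignore"):
        di = np.where(total > 0, wins / total, np.nan)
    np.fill_diagonal(di, np.nan)
    fought = np.isfinite(di)
    n_dyads = fought.sum(axis=1)
    with np.errstate(invalid="ignore"):
        adi = np.where(n_dyads > 0, np.nansum(np.where(fought, di, 0.0), axis=1)
                       / np.maximum(n_dyads, 1), np.nan)
    key = np.where(np.isnan(adi), -np.inf, adi)
    order = np.lexsort((np.arange(len(adi)), -key))
    ranks = np.empty(len(adi), dtype=int)
    ranks[order] = np.arange(1, len(adi) + 1)
    return adi, ranks


# --------------------------------------------------------------------------
# Interaction matrices
# --------------------------------------------------------------------------

STRATA = ("groom_given", "pc_affil_received_by_role",
          "pc_affil_solicited_by_role", "grooming_in_other_context")


def _female_positions(females) -> tuple[np.ndarray, dict[int, int]]:
    ids = np.asarray(sorted(int(f) for f in females))
    return ids, {int(f): k for k, f in enumerate(ids)}


def build_matrices(log: EventLog, females, stratum: str, role: str | None = None,
                   result: PCMCResult | None = None) -> np.ndarray:
    """Ordered female-dyad count matrix for one stratum over the collection
    window.

    ``groom_given``: cell (i, j) = grooms i -> j.
    ``pc_affil_received_by_role`` / ``pc_affil_solicited_by_role``: cell
    (focal, bystander) = PC-window contacts for windows with the given role.
    ``grooming_in_other_context``: grooms i -> j excluding those inside any
    PC window whose focal is i or j (so post-conflict affiliation is never
    correlated with its own events).
    """
    if stratum not in STRATA:
        raise ValueError(f"unknown stratum {stratum!r}; choose from {STRATA}")
    ids, pos = _female_positions(females)
    n = len(ids)
    mat = np.zeros((n, n), dtype=np.int64)

    if stratum in ("pc_affil_received_by_role", "pc_affil_solicited_by_role"):
        if role not in ("aggressor", "victim"):
            raise ValueError("role must be 'aggressor' or 'victim' for PC strata")
        if result is None:
            result = analyze_log(log, females)
        direction = "received" if stratum == "pc_affil_received_by_role" else "solicited"
        sel = result.contacts[(result.contacts.role == role)
                              & (result.contacts.direction == direction)]
        for row in sel.itertuples(index=False):
            mat[pos[row.focal], pos[row.bystander]] += 1
        return mat

    grooms = np.flatnonzero((log.event == EVENT_GROOM) & log.collected)
    actor = log.actor[grooms]
    partner = log.partner[grooms]
    in_females = np.isin(actor, ids) & np.isin(partner, ids)
    grooms, actor, partner = grooms[in_females], actor[in_females], partner[in_females]

    keep = np.ones(len(grooms), dtype=bool)
    if stratum == "grooming_in_other_context":
        if result is None:
            result = analyze_log(log, females)
        excluded = set()
        for w in result.windows.itertuples(index=False):
            lo = np.searchsorted(grooms, w.anchor, side="right")
            hi = np.searchsorted(grooms, w.a3, side="right")
            for k in range(lo, hi):
                if actor[k] == w.focal or partner[k] == w.focal:
                    excluded.add(k)
        if excluded:
            keep[list(excluded)] = False

    for a, p in zip(actor[keep], partner[keep]):
        mat[pos[int(a)], pos[int(p)]] += 1
    return mat


# --------------------------------------------------------------------------
# TauKr
# --------------------------------------------------------------------------

def kendall_tau_b(x, y) -> float:
    """Kendall's tau-b for two short vectors (NaN when either is constant)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    dx = np.sign(x[:, None] - x[None, :])
    dy = np.sign(y[:, None] - y[None, :])
    iu = np.triu_indices(len(x), k=1)
    dx, dy = dx[iu], dy[iu]
    n0 = len(dx)
    tx = n0 - np.count_nonzero(dx)
    ty = n0 - np.count_nonzero(dy)
    denom = (n0 - tx) * (n0 - ty)
    if denom == 0:
        return float("nan")
    return float((dx * dy).sum() / np.sqrt(denom))


def taukr_statistic(x_mat: np.ndarray, y_mat: np.ndarray) -> float:
    """Mean over rows of Kendall's tau-b between the rows of X and Y,
    diagonal cells excluded; rows where either side is constant are skipped."""
    x_mat = np.asarray(x_mat, dtype=float)
    y_mat = np.asarray(y_mat, dtype=float)
    if x_mat.shape != y_mat.shape or x_mat.shape[0] != x_mat.shape[1]:
        raise ValueError("matrices must be square and of identical shape")
    n = x_mat.shape[0]
    taus = []
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        t = kendall_tau_b(x_mat[i, mask], y_mat[i, mask])
        mask[i] = True
        if np.isfinite(t):
            taus.append(t)
    if not taus:
        raise ValueError("all rows constant: TauKr undefined")
    return float(np.mean(taus))


@dataclass
class TauKrResult:
    statistic: float
    p_value: float
    n_permutations: int
    tail: str


def taukr(x_mat, y_mat, n_perm: int = 1000, tail: str = "one",
          rng=None) -> TauKrResult:
    """TauKr with a permutation null: the identities of Y's rows and columns
    are permuted jointly; one-tailed tests positive association,
    two-tailed doubles the smaller tail."""
    if tail not in ("one", "two"):
        raise ValueError("tail must be 'one' or 'two'")
    if rng is None:
        rng = np.random.default_rng()
    y_mat = np.asarray(y_mat, dtype=float)
    obs = taukr_statistic(x_mat, y_mat)
    n = y_mat.shape[0]
    ge = le = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        sp = taukr_statistic(x_mat, y_mat[np.ix_(perm, perm)])
        ge += sp >= obs
        le += sp <= obs
    p_ge = (1 + ge) / (n_perm + 1)
    p_le = (1 + le) / (n_perm + 1)
    p = p_ge if tail == "one" else min(1.0, 2.0 * min(p_ge, p_le))
    return TauKrResult(obs, float(p), n_perm, tail)


#: The eight social-relationship correlations computed per role: PC
#: affiliation received (R) and solicited (S) by the focal from/to each
#: bystander, and grooming in other contexts (G, cell (i, j) = i grooms j).
TABLE_CORRELATIONS = (
    ("received_vs_directed_pc", "R", "S"),          # reciprocity of PC affiliation
    ("received_vs_grooming_received", "R", "Gt"),
    ("received_vs_grooming_given", "R", "G"),
    ("solicited_vs_solicitation_received", "S", "St"),
    ("solicited_vs_grooming_given", "S", "G"),
    ("solicited_vs_grooming_received", "S", "Gt"),
    ("grooming_vs_pc_received", "Gsym", "Rsym"),
    ("grooming_vs_pc_solicited", "Gsym", "Ssym"),
)


def table_correlations(log: EventLog, females, role: str,
                       result: PCMCResult | None = None, n_perm: int = 1000,
                       rng=None) -> pd.DataFrame:
    """The eight TauKr correlations between post-conflict affiliation and
    grooming relationships for one run and one focal role."""
    if result is None:
        result = analyze_log(log, females)
    if rng is None:
        rng = np.random.default_rng()
    r_mat = build_matrices(log, females, "pc_affil_received_by_role", role, result)
    s_mat = build_matrices(log, females, "pc_affil_solicited_by_role", role, result)
    g_mat = build_matrices(log, females, "grooming_in_other_context", result=result)
    mats = {"R": r_mat, "S": s_mat, "G": g_mat, "Gt": g_mat.T, "St": s_mat.T,
            "Rsym": r_mat + r_mat.T, "Ssym": s_mat + s_mat.T, "Gsym": g_mat + g_mat.T}
    rows = []
    for name, xk, yk in TABLE_CORRELATIONS:
        res = taukr(mats[xk], mats[yk], n_perm=n_perm, tail="one", rng=rng)
        rows.append((name, role, res.statistic, res.p_value))
    return pd.DataFrame(rows, columns=["correlation", "role", "statistic", "p"])


# --------------------------------------------------------------------------
# Rank-sum tests and probability combination
# --------------------------------------------------------------------------

def mann_whitney_u(a, b, alternative: str = "two-sided") -> tuple[float, float]:
    """U = #{(x, y): x > y} + half the ties over a x b; p by normal
    approximation with tie correction (exact for small tie-free samples)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.mannwhitneyu(a, b, alternative=alternative)
    return float(res.statistic), float(res.pvalue)


def wilcoxon_matched(a, b, alternative: str = "two-sided") -> tuple[float, float]:
    """Signed-rank test on paired samples; statistic = sum of the ranks of
    the positive differences (zero differences dropped); exact p for small
    tie-free samples."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    d = a - b
    d = d[d != 0]
    if len(d) == 0:
        raise ValueError("all differences are zero: test undefined")
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    res = stats.wilcoxon(d, alternative=alternative,
                         method="exact" if len(d) <= 25 and len(np.unique(np.abs(d))) == len(d)
                         else "approx")
    return w_plus, float(res.pvalue)


def hochberg_combine(p_values, alpha: float = 0.05) -> tuple[np.ndarray, dict]:
    """Hochberg's step-up procedure over one p-value per run.

    Rejects every hypothesis up to the largest i (counting from the largest
    p) with p_(i) <= alpha / i.  The report carries the step-up adjusted
    p-values (k * p_(k) for the k-th smallest, monotonized from the top) and
    their minimum as the combined cross-run probability.
    """
    p = np.asarray(p_values, dtype=float)
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    m = len(p)
    order = np.argsort(p)[::-1]  # descending
    mult = np.arange(1, m + 1)   # 1 for the largest p, m for the smallest
    adj_sorted = np.minimum.accumulate(p[order] * mult)
    adj = np.empty(m)
    adj[order] = np.minimum(adj_sorted, 1.0)
    rejected = adj <= alpha
    report = {"adjusted_p": adj, "combined_p": float(adj.min()),
              "n_rejected": int(rejected.sum()), "alpha": alpha}
    return rejected, report


def aggressor_victim_rank_test(per_run_logs, per_run_results, females,
                               direction: str) -> tuple[float, float, int, int]:
    """Do aggressors outrank victims (by ADI) among the conflicts followed by
    a PC-window contact of the given direction?  One-tailed Mann-Whitney on
    the focal ADIs pooled over runs; returns (U, p, n_aggressor, n_victim)."""
    agg_vals, vct_vals = [], []
    for log, result in zip(per_run_logs, per_run_results):
        adi, _ = average_dominance_index(build_wins_matrix(log))
        sel = result.pairs[(result.pairs.direction == direction)
                           & result.pairs.pc_block.notna()]
        for row in sel.itertuples(index=False):
            (agg_vals if row.role == "aggressor" else vct_vals).append(adi[row.focal])
    u, p = mann_whitney_u(agg_vals, vct_vals, alternative="greater")
    return u, p, len(agg_vals), len(vct_vals)
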