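"""Statistics of coupling change between seizure phases and a control period.

For every unordered pair of contacts on distinct electrodes, the pair's h²
during a given phase of each seizure is differenced against the seizure's
control-period h², giving one difference per seizure.  A two-sided Wilcoxon
signed-rank test per pair (seizures as replicates) asks whether the
differences are centred at zero; the Benjamini-Hochberg step-up procedure at
FDR q = 0.05 controls for the many pairs tested, and the k pairs with the
smallest p-values are reported with their difference vectors for boxplots.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .clustering import electrode_of
from .signal_io import Phase


@dataclass
class PairDifferenceSeries:
    pair: tuple  # (contact_a, contact_b), sorted, distinct electrodes
    phase: Phase
    diffs: np.ndarray  # one (phase h2 - control h2) per contributing seizure
    seizure_ids: list

    @property
    def label(self) -> str:
        return f"{self.pair[0]}-{self.pair[1]}"


@dataclass
class SignedRankResult:
    pair: tuple
    phase: Phase
    statistic: float  # Wilcoxon W (sum of positive-difference ranks)
    p_two_sided: float
    n_effective: int  # nonzero differences

    @property
    def label(self) -> str:
        return f"{self.pair[0]}-{self.pair[1]}"


@dataclass
class BHResult:
    q: float
    pvalues: np.ndarray  # in input order
    order: np.ndarray  # argsort of pvalues
    critical: np.ndarray  # c_i = i*q/m for the sorted sequence
    cutoff_index: int  # number of rejected tests (prefix length of sorted order)
    significant: np.ndarray  # boolean mask in input order

    @property
    def n_significant(self) -> int:
        return int(self.cutoff_index)


def _collapse(v_ab: float, v_ba: float, how: str) -> float:
    vals = [v for v in (v_ab, v_ba) if np.isfinite(v)]
    if not vals:
        return np.nan
    return max(vals) if how == "max" else float(np.mean(vals))


def pair_differences(event_matrices, control_matrices, phase,
                     collapse: str = "max"):
    """Per-pair difference vectors (phase h² minus control h²) across seizures.

    event_matrices: coupling matrices whose events carry seizure_id and phase
    (matrices of other phases are ignored).  control_matrices: one control
    matrix per seizure_id (mapping or list).  A seizure lacking the phase
    simply contributes nothing to that phase.  The two directed h² values of a
    pair collapse to their maximum (default) or mean.
    """
    phase = Phase(phase)
    if collapse not in ("max", "mean"):
        raise ValueError("collapse must be 'max' or 'mean'")
    if not isinstance(control_matrices, dict):
        control_matrices = {cm.event.seizure_id: cm for cm in control_matrices}
    per_pair: dict = {}
    for cm in event_matrices:
        if cm.event is None or cm.event.phase != phase:
            continue
        sid = cm.event.seizure_id
        if sid not in control_matrices:
            raise ValueError(f"no control matrix for seizure {sid}")
        ctrl = control_matrices[sid]
        labels = cm.labels
        for i in range(len(labels)):
            for j in range(i + 1, len(labels)):
                a, b = labels[i], labels[j]
                if electrode_of(a) == electrode_of(b):
                    continue
                d = (_collapse(cm.value(a, b), cm.value(b, a), collapse)
                     - _collapse(ctrl.value(a, b), ctrl.value(b, a), collapse))
                per_pair.setdefault((a, b), []).append((sid, d))
    out = []
    for pair in sorted(per_pair):
        entries = sorted(per_pair[pair])
        out.append(PairDifferenceSeries(
            pair=pair, phase=phase,
            diffs=np.array([d for _, d in entries]),
            seizure_ids=[s for s, _ in entries]))
    return out


def signed_rank(series_or_diffs, pair=("x", "y"), phase=Phase.onset) -> SignedRankResult:
    """Two-sided Wilcoxon signed-rank test of zero-centred differences.

    Zero differences are dropped.  The exact null distribution is used for up
    to 25 nonzero tie-free differences; otherwise the tie-corrected normal
    approximation.  All-zero input yields W = 0, p = 1.
    """
    if isinstance(series_or_diffs, PairDifferenceSeries):
        diffs = series_or_diffs.diffs
        pair = series_or_diffs.pair
        phase = series_or_diffs.phase
    else:
        diffs = np.asarray(series_or_diffs, dtype=float)
    if diffs.size < 1:
        raise ValueError("need at least one difference")
    nz = diffs[diffs != 0]
    if nz.size == 0:
        return SignedRankResult(pair=pair, phase=Phase(phase), statistic=0.0,
                                p_two_sided=1.0, n_effective=0)
    ties = np.unique(np.abs(nz)).size < nz.size
    method = "exact" if (nz.size <= 25 and not ties) else "approx"
    res = sps.wilcoxon(nz, alternative="two-sided", method=method, correction=False)
    w_plus = float(np.sum(sps.rankdata(np.abs(nz))[nz > 0]))
    return SignedRankResult(pair=pair, phase=Phase(phase),
                            statistic=w_plus,
                            p_two_sided=float(min(res.pvalue, 1.0)),
                            n_effective=int(nz.size))


def bh_adjust(pvalues, q: float = 0.05) -> BHResult:
    """Benjamini-Hochberg step-up at FDR level q.

    Sorted p-values p_(1) <= ... <= p_(m) are compared to critical values
    c_i = i*q/m; every test up to the largest i with p_(i) <= c_i is
    significant (a prefix of the sorted order).
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    m = p.size
    order = np.argsort(p, kind="stable")
    crit = (np.arange(1, m + 1) * q) / m
    below = p[order] <= crit
    cutoff = int(np.max(np.nonzero(below)[0]) + 1) if below.any() else 0
    sig = np.zeros(m, dtype=bool)
    sig[order[:cutoff]] = True
    return BHResult(q=q, pvalues=p, order=order, critical=crit,
                    cutoff_index=cutoff, significant=sig)


def top_pairs(results, series=None, k: int = 25):
    """The k tests with smallest p-values (ascending p, ties by pair label).

    When the matching difference series are supplied, also returns a long
    table (pair, phase, seizure_id, diff) for the top pairs, ready for
    boxplots.
    """
    results = list(results)
    if k > len(results):
        warnings.warn(f"k={k} exceeds the {len(results)} available tests; returning all")
        k = len(results)
    ranked = sorted(results, key=lambda r: (r.p_two_sided, r.label))[:k]
    if series is None:
        return ranked, None
    by_pair = {(s.pair, s.phase): s for s in series}
    import pandas as pd

    rows = []
    for r in ranked:
        s = by_pair.get((r.pair, r.phase))
        if s is None:
            continue
        for sid, d in zip(s.seizure_ids, s.diffs):
            rows.append({"pair": r.label, "phase": r.phase.value,
                         "seizure_id": sid, "diff": d})
    return ranked, pd.DataFrame(rows, columns=["pair", "phase", "seizure_id", "diff"])


def phase_change_table(event_matrices, control_matrices, phase,
                       q: float = 0.05, k: int = 25, collapse: str = "max"):
    """End-to-end per-phase analysis: differences -> signed-rank -> B-H -> top-k.

    Returns (results DataFrame, BHResult, boxplot DataFrame).
    """
    import pandas as pd

    series = pair_differences(event_matrices, control_matrices, phase, collapse)
    if not series:
        return (pd.DataFrame(columns=["pair", "phase", "n", "W", "p",
                                      "bh_critical", "significant"]),
                None, pd.DataFrame(columns=["pair", "phase", "seizure_id", "diff"]))
    results = [signed_rank(s) for s in series]
    bh = bh_adjust([r.p_two_sided for r in results], q=q)
    rank_of = np.empty(len(results), dtype=int)
    rank_of[bh.order] = np.arange(len(results))
    table = pd.DataFrame([
        {"pair": r.label, "phase": r.phase.value, "n": r.n_effective,
         "W": r.statistic, "p": r.p_two_sided,
         "bh_critical": bh.critical[rank_of[i]],
         "significant": bool(bh.significant[i])}
        for i, r in enumerate(results)
    ]).sort_values(["p", "pair"], kind="stable").reset_index(drop=True)
    _, box = top_pairs(results, series, k=k)
    return table, bh, box
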