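"""Walking-speed mode estimation by univariate Gaussian mixtures.

Each participant's stride-speed distribution is modeled as a K-component
Gaussian mixture fitted by expectation-maximization, for K = 1..9 and two
variance families (``equal``: one pooled variance; ``varying``: one variance
per component, mirroring the univariate "E"/"V" model family of classical
mixture software). The number of walking-speed modes is the K of the fit
with the lowest Bayesian Information Criterion

    BIC = -2 log L + p log n,      p = 2K (equal) or 3K - 1 (varying),

with ties broken toward the smaller K and then the equal-variance family
(parsimony). Modes are estimated separately per bout-duration class
(>10 s, 10–30 s, >30 s) from the strides pooled over that class's bouts.

EM is initialized at equally spaced quantile means with sample-SD widths and
equal weights; additional restarts jitter the means. Restart seeds derive
from the configuration seed only, never from the data, so fits are
permutation-invariant. Each restart runs a short burn-in and only the
restart with the best burn-in log-likelihood is polished to convergence.

A fixed-stride-count resampling utility reproduces sample-size-controlled
re-analysis: each day's time-ordered speed sequence is linearly interpolated
onto a fixed number of equally spaced positions (up- or down-sampling), then
days are pooled before mixture fitting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .bouts import WalkingBout
from .config import GAIT_CLASS_LABELS, ModesConfig

__all__ = [
    "Mixture1DResults",
    "GaussianMixture1D",
    "ModeEstimate",
    "InsufficientDataError",
    "select_modes_bic",
    "resample_strides",
    "modes_by_threshold",
    "mode_count_table",
]

_LOG_2PI = float(np.log(2.0 * np.pi))


class InsufficientDataError(ValueError):
    """Raised when no (K, family) pair is feasible for the sample."""


@dataclass
class Mixture1DResults:
    """Fitted univariate Gaussian mixture.

    Components are sorted by ascending mean. ``loglik_trace`` holds the
    log-likelihood after every EM iteration of the winning restart
    (burn-in followed by polish), which is non-decreasing up to round-off.
    """

    k: int
    family: str
    weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    loglik: float
    n: int
    n_params: int
    bic: float
    converged: bool
    degenerate: bool
    n_iter: int
    loglik_trace: np.ndarray = field(repr=False, default=None)

    def pdf(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)[:, None]
        comp = np.exp(
            -0.5 * ((x - self.means) / self.sds) ** 2
        ) / (self.sds * np.sqrt(2.0 * np.pi))
        return comp @ self.weights

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "component": np.arange(1, self.k + 1),
                "weight": self.weights,
                "mean_mps": self.means,
                "sd_mps": self.sds,
            }
        )


def _n_params(k: int, family: str) -> int:
    # weights (K-1) + means (K) + variances (K or 1)
    return 3 * k - 1 if family == "varying" else 2 * k


def _log_density(x, weights, means, sds):
    """(n, K) component log densities + log weights."""
    z = (x[:, None] - means[None, :]) / sds[None, :]
    return (
        np.log(weights)[None, :]
        - np.log(sds)[None, :]
        - 0.5 * (z * z + _LOG_2PI)
    )


def _loglik(x, weights, means, sds) -> float:
    return float(logsumexp(_log_density(x, weights, means, sds), axis=1).sum())


def _em_iterate(x, weights, means, sds, family, var_floor, max_iter, rel_tol):
    """Run EM from the given parameters; returns params, trace, converged.

    The E-step and the M-step moment sums reuse preallocated buffers and
    BLAS matrix-vector products; responsibilities are computed with the
    usual max-shifted exponentials for stability.
    """
    n = x.size
    k = means.size
    # fixed moment matrix: one GEMM per M-step gives (sum r, sum rx, sum rx^2)
    A = np.vstack([np.ones(n), x, x * x])
    Z = np.empty((n, k))
    trace = []
    prev_ll = -np.inf
    converged = False
    degenerate = False
    weights = weights.copy()
    means = means.copy()
    sds = sds.copy()
    for _ in range(max_iter):
        # E-step with unshifted densities (speeds are O(1) so overflow is
        # impossible); rows that underflow to zero fall back to the
        # max-shifted form
        np.subtract(x[:, None], means[None, :], out=Z)
        Z /= sds[None, :]
        np.multiply(Z, Z, out=Z)
        Z *= -0.5
        np.exp(Z, out=Z)
        Z *= (weights / sds / np.sqrt(2.0 * np.pi))[None, :]
        s = Z.sum(axis=1)
        if s.min() <= 0.0:
            logd = _log_density(x, weights, means, sds)
            m = logd.max(axis=1)
            Z[:] = np.exp(logd - m[:, None])
            s = Z.sum(axis=1)
            ll = float((m + np.log(s)).sum())
        else:
            ll = float(np.log(s).sum())
        trace.append(ll)
        Z /= s[:, None]
        # M-step from weighted raw moments (BLAS)
        mom = A @ Z
        nk = np.maximum(mom[0], 1e-300)
        sx = mom[1]
        sxx = mom[2]
        weights = nk / n
        means = sx / nk
        if family == "equal":
            var_pool = max((sxx.sum() - (nk * means * means).sum()) / n, 0.0)
            var = np.full(k, var_pool)
        else:
            var = np.maximum(sxx / nk - means * means, 0.0)
        if np.any(var < var_floor):
            degenerate = True
            var = np.maximum(var, var_floor)
        sds = np.sqrt(var)
        if np.isfinite(prev_ll) and abs(ll - prev_ll) <= rel_tol * max(1.0, abs(ll)):
            converged = True
            break
        prev_ll = ll
    trace.append(_loglik(x, weights, means, sds))
    return (weights, means, sds), np.asarray(trace), converged, degenerate


class GaussianMixture1D:
    """Univariate Gaussian mixture model for a speed sample.

    Parameters
    ----------
    speeds : array-like
        Stride speeds in m/s; must be finite and positive.
    k : int
        Number of mixture components.
    family : {"varying", "equal"}
        Per-component or pooled variance.
    """

    def __init__(self, speeds, k: int, family: str = "varying"):
        x = np.asarray(speeds, dtype=float).ravel()
        if x.size == 0 or not np.all(np.isfinite(x)) or np.any(x <= 0):
            raise ValueError("speeds must be finite and positive")
        if family not in ("varying", "equal"):
            raise ValueError("family must be 'varying' or 'equal'")
        if k < 1:
            raise ValueError("k must be >= 1")
        self.x = x
        self.k = int(k)
        self.family = family

    @property
    def feasible(self) -> bool:
        return np.unique(self.x).size >= 2 * self.k

    def _initial_params(self, jitter_rng=None):
        x, k = self.x, self.k
        q = (np.arange(k) + 0.5) / k
        means = np.quantile(x, q)
        sd = max(float(x.std()), 1e-6)
        if jitter_rng is not None:
            means = means + jitter_rng.normal(0.0, sd / 2.0, k)
        sds = np.full(k, max(sd / max(k, 1), 1e-6))
        weights = np.full(k, 1.0 / k)
        return weights, means, sds

    def fit(self, cfg: ModesConfig | None = None) -> Mixture1DResults:
        """Fit by EM with seeded jittered restarts; returns sorted components."""
        cfg = (cfg or ModesConfig()).validate()
        if not self.feasible:
            raise InsufficientDataError(
                f"need at least {2 * self.k} distinct values for K={self.k}"
            )
        x = self.x
        var_floor = cfg.variance_floor_factor * max(float(x.var()), 1e-12)
        fam_idx = 0 if self.family == "equal" else 1

        # burn in every restart on a deterministic subsample (a cheap
        # mclust-style initialization refinement), rank by full-data
        # log-likelihood, then polish the winner on the full sample
        step = max(1, x.size // 1024)
        x_sub = x[::step] if x.size > 2048 else x
        if np.unique(x_sub).size < 2 * self.k:
            x_sub = x
        candidates = []
        for r in range(cfg.n_init):
            if r == 0:
                init = self._initial_params()
            else:
                rng = np.random.default_rng(
                    np.random.SeedSequence(
                        [int(cfg.seed) % (2**31), self.k, fam_idx, r]
                    )
                )
                init = self._initial_params(rng)
            params, _, _, _ = _em_iterate(
                x_sub, *init, self.family, var_floor,
                min(cfg.burn_in_iter, cfg.max_iter), cfg.rel_tol,
            )
            candidates.append((_loglik(x, *params), params))
        _, params = max(candidates, key=lambda c: c[0])
        params, trace, conv, degen = _em_iterate(
            x, *params, self.family, var_floor, cfg.max_iter, cfg.rel_tol
        )
        weights, means, sds = params
        order = np.argsort(means, kind="stable")
        weights, means, sds = weights[order], means[order], sds[order]
        ll = float(trace[-1])
        p = _n_params(self.k, self.family)
        n = x.size
        return Mixture1DResults(
            k=self.k,
            family=self.family,
            weights=weights,
            means=means,
            sds=sds,
            loglik=ll,
            n=n,
            n_params=p,
            bic=-2.0 * ll + p * np.log(n),
            converged=bool(conv),
            degenerate=bool(degen),
            n_iter=len(trace) - 1,
            loglik_trace=trace,
        )


@dataclass
class ModeEstimate:
    """BIC-selected mode count for one participant and duration class."""

    participant_id: str
    class_label: str
    k: int
    fit: Mixture1DResults
    bic_table: pd.DataFrame

    def summary(self) -> pd.DataFrame:
        return self.fit.summary().assign(
            participant_id=self.participant_id, duration_class=self.class_label
        )


def select_modes_bic(
    speeds,
    cfg: ModesConfig | None = None,
    participant_id: str = "",
    class_label: str = "",
) -> ModeEstimate:
    """Fit every feasible (K, family) pair and select the lowest BIC.

    Ties (BIC within 1e-9) break toward smaller K, then the equal-variance
    family. Raises :class:`InsufficientDataError` when nothing is feasible.
    """
    cfg = (cfg or ModesConfig()).validate()
    x = np.asarray(speeds, dtype=float).ravel()
    rows = []
    fits = {}
    for k in range(cfg.k_min, cfg.k_max + 1):
        for family in cfg.variance_families:
            model = GaussianMixture1D(x, k, family)
            if not model.feasible:
                rows.append(
                    {"k": k, "family": family, "feasible": False,
                     "loglik": np.nan, "n_params": _n_params(k, family),
                     "bic": np.nan, "converged": False, "degenerate": False}
                )
                continue
            fit = model.fit(cfg)
            fits[(k, family)] = fit
            rows.append(
                {"k": k, "family": family, "feasible": True,
                 "loglik": fit.loglik, "n_params": fit.n_params,
                 "bic": fit.bic, "converged": fit.converged,
                 "degenerate": fit.degenerate}
            )
    table = pd.DataFrame(rows)
    feas = table[table["feasible"]]
    if feas.empty:
        raise InsufficientDataError("insufficient data: no feasible mixture fit")
    best_bic = feas["bic"].min()
    tied = feas[feas["bic"] <= best_bic + 1e-9].copy()
    tied["fam_rank"] = (tied["family"] != "equal").astype(int)
    sel = tied.sort_values(["k", "fam_rank"]).iloc[0]
    fit = fits[(int(sel["k"]), sel["family"])]
    return ModeEstimate(
        participant_id=participant_id,
        class_label=class_label,
        k=int(sel["k"]),
        fit=fit,
        bic_table=table.drop(columns=[c for c in ("fam_rank",) if c in table]),
    )


# ---------------------------------------------------------------------------
# fixed-stride-count resampling


def resample_strides(day_sequences: list, target: int) -> np.ndarray:
    """Resample each day's speed sequence to ``target`` strides and pool.

    Each day's time-ordered sequence, indexed 0..m-1, is linearly
    interpolated at ``target`` equally spaced positions over [0, m-1]
    (up- or down-sampling as needed); endpoints are always preserved.
    Days with fewer than two strides are skipped with a warning.
    """
    if target < 2:
        raise ValueError("target must be >= 2")
    pooled = []
    for i, seq in enumerate(day_sequences):
        seq = np.asarray(seq, dtype=float).ravel()
        m = seq.size
        if m < 2:
            warnings.warn(f"day {i} has < 2 strides; skipped", stacklevel=2)
            continue
        pos = np.linspace(0.0, m - 1.0, target)
        pooled.append(np.interp(pos, np.arange(m), seq))
    if not pooled:
        return np.array([])
    return np.concatenate(pooled)


# ---------------------------------------------------------------------------
# per-duration-class driver


def modes_by_threshold(
    bouts: list[WalkingBout],
    cfg: ModesConfig | None = None,
    class_labels: tuple[str, ...] = GAIT_CLASS_LABELS,
    min_strides: int = 100,
    resample_target: int | None = None,
) -> tuple[dict, pd.DataFrame]:
    """Mode estimates per participant and duration class.

    Pools stride speeds from each participant's bouts in each duration
    class and runs BIC selection. Participants contributing fewer than
    ``min_strides`` strides to a class are omitted from that class (logged
    in the returned table with k = NaN). If ``resample_target`` is given,
    each participant-day's pooled speeds are first resampled to that fixed
    stride count.

    Returns ``(estimates, log)`` where ``estimates`` maps
    (participant_id, class_label) to :class:`ModeEstimate`.
    """
    cfg = (cfg or ModesConfig()).validate()
    by_participant: dict[str, list[WalkingBout]] = {}
    for b in bouts:
        by_participant.setdefault(b.participant_id, []).append(b)
    estimates: dict[tuple[str, str], ModeEstimate] = {}
    log_rows = []
    for pid in sorted(by_participant):
        for label in class_labels:
            members = [
                b for b in by_participant[pid] if label in b.duration_labels
            ]
            if resample_target is not None:
                day_seqs = []
                for day in sorted({b.day for b in members}):
                    day_strides = pd.concat(
                        [b.strides for b in members if b.day == day],
                        ignore_index=True,
                    ).sort_values("stride_start_s")
                    day_seqs.append(day_strides["speed_mps"].to_numpy())
                speeds = resample_strides(day_seqs, resample_target) if day_seqs else np.array([])
            else:
                speeds = (
                    np.concatenate(
                        [b.strides["speed_mps"].to_numpy() for b in members]
                    )
                    if members
                    else np.array([])
                )
            if speeds.size < max(min_strides, 2 * cfg.k_min):
                log_rows.append(
                    {"participant_id": pid, "duration_class": label,
                     "n_strides": int(speeds.size), "k": np.nan,
                     "note": "omitted: too few strides"}
                )
                continue
            est = select_modes_bic(speeds, cfg, pid, label)
            estimates[(pid, label)] = est
            log_rows.append(
                {"participant_id": pid, "duration_class": label,
                 "n_strides": int(speeds.size), "k": est.k, "note": ""}
            )
    return estimates, pd.DataFrame(log_rows)


def mode_count_table(
    estimates: dict,
    cohorts: dict[str, str],
    k_range: tuple[int, int] = (1, 9),
) -> pd.DataFrame:
    """Cohort x duration-class contingency of selected mode counts.

    One row per (cohort, duration class); one column per K with the number
    of participants whose selected mode count is K — the layout used to
    report the distribution of walking-speed modes across bout durations.
    """
    ks = list(range(k_range[0], k_range[1] + 1))
    rows = {}
    for (pid, label), est in estimates.items():
        cohort = cohorts.get(pid, "all")
        key = (cohort, label)
        if key not in rows:
            rows[key] = {f"K={k}": 0 for k in ks}
        rows[key][f"K={est.k}"] = rows[key].get(f"K={est.k}", 0) + 1
    out = pd.DataFrame(
        [
            {"cohort": cohort, "duration_class": label, **counts}
            for (cohort, label), counts in sorted(rows.items())
        ]
    )
    return out
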