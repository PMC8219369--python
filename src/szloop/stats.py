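"""Endpoint statistics on detected seizures.

Per animal: the distribution of seizure durations in light-on vs light-off
conditions is compared with a two-sample Kolmogorov-Smirnov test, and the
normalized change in median duration is computed as
(median_on − median_off) / median_off.  Across animals: per-animal medians
are compared with a paired Wilcoxon signed-rank test (exact for n ≤ 25),
normalized changes between opsin and control cohorts with a two-sample
t-test (Welch by default), interseizure intervals with a paired Wilcoxon,
and median Racine severity with a paired t-test.  All tests are two-sided.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sst

from .cohort import AnimalEvents

__all__ = [
    "AnimalResult",
    "GroupResult",
    "ks_durations",
    "group_wilcoxon_medians",
    "normalized_change",
    "normalized_change_test",
    "interseizure_analysis",
    "severity_paired_test",
    "analyze_animal",
    "analyze_group",
]


@dataclass
class AnimalResult:
    animal_id: str
    durations_on: np.ndarray
    durations_off: np.ndarray
    median_on: float
    median_off: float
    ks_statistic: float
    ks_p: float
    normalized_change: float
    interseizure_on: np.ndarray = field(default_factory=lambda: np.array([]))
    interseizure_off: np.ndarray = field(default_factory=lambda: np.array([]))
    severity_on: np.ndarray = field(default_factory=lambda: np.array([]))
    severity_off: np.ndarray = field(default_factory=lambda: np.array([]))


@dataclass
class GroupResult:
    medians_on: np.ndarray
    medians_off: np.ndarray
    wilcoxon_W: float
    wilcoxon_p: float
    t_statistic: float | None = None
    t_p: float | None = None
    interseizure_W: float | None = None
    interseizure_p: float | None = None
    severity_T: float | None = None
    severity_p: float | None = None


def ks_durations(on, off) -> tuple[float, float]:
    """Two-sample two-sided KS test on duration distributions."""
    on = np.asarray(on, dtype=float)
    off = np.asarray(off, dtype=float)
    if on.size < 3 or off.size < 3:
        raise ValueError("each condition needs at least 3 durations")
    res = sst.ks_2samp(on, off, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def _paired_wilcoxon(x, y, exact_max_n: int = 25) -> tuple[float, float]:
    """Two-sided paired Wilcoxon: exact for small n, else normal approx with
    continuity correction.  All-zero differences degenerate to (0, 1)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    d = x - y
    if np.all(d == 0):
        return 0.0, 1.0
    method = "exact" if d.size <= exact_max_n else "approx"
    kwargs = {"correction": True} if method == "approx" else {}
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # exact method warns on ties
        res = sst.wilcoxon(x, y, alternative="two-sided", method=method, **kwargs)
    return float(res.statistic), float(res.pvalue)


def group_wilcoxon_medians(per_animal_medians) -> tuple[float, float]:
    """Paired Wilcoxon on (median_on, median_off) pairs, one per animal."""
    pairs = np.asarray(per_animal_medians, dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] != 2:
        raise ValueError("expected an (n_animals, 2) array of medians")
    return _paired_wilcoxon(pairs[:, 0], pairs[:, 1])


def normalized_change(median_on: float, median_off: float) -> float:
    """(median_on − median_off) / median_off."""
    if median_off <= 0:
        raise ValueError("normalized change undefined for median_off <= 0")
    return (median_on - median_off) / median_off


def normalized_change_test(
    chr2_changes, control_changes, equal_var: bool = False
) -> tuple[float, float]:
    """Two-sided two-sample t-test on per-animal normalized changes.

    Welch (unequal variance) by default; set ``equal_var=True`` for the
    classic pooled form.
    """
    a = np.asarray(chr2_changes, dtype=float)
    b = np.asarray(control_changes, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 animals")
    if np.var(a) == 0 and np.var(b) == 0:
        raise ValueError("zero variance in both groups")
    res = sst.ttest_ind(a, b, equal_var=equal_var)
    return float(res.statistic), float(res.pvalue)


def _interseizure_medians(events) -> tuple[float, float] | None:
    """Per-animal median interval following stimulated vs unstimulated events.

    The interval after an event runs from its offset to the next onset and is
    assigned to that event's condition; the last event (undefined trailing
    interval) is excluded.
    """
    df = events.sort_values("onset").reset_index(drop=True)
    if len(df) < 2:
        return None
    gaps = df["onset"].to_numpy()[1:] - df["offset"].to_numpy()[:-1]
    cond = df["stimulated"].to_numpy()[:-1]
    on, off = gaps[cond], gaps[~cond]
    if on.size == 0 or off.size == 0:
        return None
    return float(np.median(on)), float(np.median(off))


def interseizure_analysis(animals: list[AnimalEvents]) -> tuple[float, float, np.ndarray]:
    """Paired Wilcoxon on per-animal median interseizure intervals.

    Animals with fewer than two events (or with all events in one condition)
    are excluded.  Returns (W, p, per-animal medians array).
    """
    pairs = [m for an in animals if (m := _interseizure_medians(an.events)) is not None]
    if len(pairs) < 2:
        raise ValueError("need at least 2 animals with defined interval medians")
    arr = np.asarray(pairs)
    W, p = _paired_wilcoxon(arr[:, 0], arr[:, 1])
    return W, p, arr


def severity_paired_test(severity_on, severity_off) -> tuple[float, float]:
    """Two-sided paired t-test on per-animal median Racine scores."""
    a = np.asarray(severity_on, dtype=float)
    b = np.asarray(severity_off, dtype=float)
    if a.size != b.size:
        raise ValueError("paired severity lists must have equal length")
    if a.size < 2:
        raise ValueError("need at least 2 animals")
    for arr in (a, b):
        if np.any((arr < 1) | (arr > 6)):
            raise ValueError("Racine scores must lie in 1..6")
    res = sst.ttest_rel(a, b)
    t = float(res.statistic)
    if np.isnan(t) and np.all(a == b):
        return 0.0, 1.0
    return t, float(res.pvalue)


def analyze_animal(animal: AnimalEvents) -> AnimalResult:
    """Per-animal endpoint summary: medians, KS test, normalized change."""
    on = animal.durations(True)
    off = animal.durations(False)
    D, p = ks_durations(on, off)
    med_on, med_off = float(np.median(on)), float(np.median(off))
    im = _interseizure_medians(animal.events)
    df = animal.events
    return AnimalResult(
        animal_id=animal.animal_id,
        durations_on=on,
        durations_off=off,
        median_on=med_on,
        median_off=med_off,
        ks_statistic=D,
        ks_p=p,
        normalized_change=normalized_change(med_on, med_off),
        interseizure_on=np.array([im[0]]) if im else np.array([]),
        interseizure_off=np.array([im[1]]) if im else np.array([]),
        severity_on=df.loc[df["stimulated"], "severity"].to_numpy(),
        severity_off=df.loc[~df["stimulated"], "severity"].to_numpy(),
    )


def analyze_group(
    chr2: list[AnimalEvents],
    controls: list[AnimalEvents] | None = None,
    equal_var: bool = False,
) -> tuple[list[AnimalResult], GroupResult]:
    """Full endpoint analysis of an opsin cohort (plus optional controls)."""
    results = [analyze_animal(a) for a in chr2]
    pairs = np.array([[r.median_on, r.median_off] for r in results])
    W, wp = group_wilcoxon_medians(pairs)
    group = GroupResult(
        medians_on=pairs[:, 0], medians_off=pairs[:, 1], wilcoxon_W=W, wilcoxon_p=wp
    )
    if controls is not None:
        ctrl_results = [analyze_animal(a) for a in controls]
        group.t_statistic, group.t_p = normalized_change_test(
            [r.normalized_change for r in results],
            [r.normalized_change for r in ctrl_results],
            equal_var=equal_var,
        )
    try:
        group.interseizure_W, group.interseizure_p, _ = interseizure_analysis(chr2)
    except ValueError:
        pass
    sev_on = [np.median(r.severity_on) for r in results if r.severity_on.size]
    sev_off = [np.median(r.severity_off) for r in results if r.severity_off.size]
    if len(sev_on) == len(sev_off) and len(sev_on) >= 2:
        group.severity_T, group.severity_p = severity_paired_test(sev_on, sev_off)
    return results, group
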