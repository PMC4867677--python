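"""Brain vital sign (BVS) scoring and elemental brain scores (EBS).

Each of the six measures earns 1-5 points by normative bracketing:
a measure within one SD of the normative mean (on the "good" side)
scores 5, then one point is lost per half-SD step toward the bad tail,
bottoming out at 1 beyond 2.5 SD. Amplitudes are scored on SIGNED
values, so for the negative components (N100, N400) "worse" means more
positive. Sub-scores A (Auditory sensation, N100), B (Basic attention,
P300) and C (Cognitive processing, N400) each sum amplitude + latency
points (max 10); the total out of 30 represents fully normative
processing. Components are weighted equally.

The elemental brain scores map each measure linearly onto [0, 1]
relative to the normative best value and range:

    EBS = 1 - |M - best| / (max - min)

so 1 is the best possible measurement and scores fall off linearly with
distance from it (clamped at 0 outside the normative span).

Group comparison helpers implement the pooled two-sample t-test (from
raw samples or printed summary statistics) with a Shapiro-Wilk normality
gate falling back to the rank-sum test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .detect import MEASURE_IDS
from .normative import NormativeStats

_COMPONENT_OF_SUBSCORE = {"A": "N100", "B": "P300", "C": "N400"}


def measure_points(value: float, stats_: NormativeStats, measure_kind: str, component: str) -> int:
    """1-5 points for one measure under the normative bracket scheme.

    ``measure_kind`` is "amplitude" or "latency". Bracket boundaries:
    exact ties resolve away from the 5-point branch (its inequality is
    strict), i.e. a value exactly one SD into the bad tail scores 4.
    """
    if not np.isfinite(value):
        raise ValueError("measure value must be finite")
    mu, sigma = stats_.mu, stats_.sigma
    if measure_kind == "amplitude" and component == "P300":
        # positive component: large amplitude good, penalize the low tail
        z = (mu - value) / sigma
    elif measure_kind == "amplitude":
        # negative components: signed value, penalize the high (positive) tail
        z = (value - mu) / sigma
    elif measure_kind == "latency":
        z = (value - mu) / sigma
    else:
        raise ValueError(f"unknown measure kind {measure_kind!r}")
    # z is "SDs into the bad tail"; 5-point branch is strict (z < 1)
    if z < 1.0:
        return 5
    if z < 1.5:
        return 4
    if z < 2.0:
        return 3
    if z < 2.5:
        return 2
    return 1


def ebs(value: float, stats_: NormativeStats) -> float:
    """Elemental brain score: linear distance from the normative best.

    1 at the best value, 0 when |M - best| spans the whole normative
    range; clamped to [0, 1] outside it.
    """
    span = stats_.max - stats_.min
    if span <= 0:
        raise ValueError("normative range is degenerate (max == min)")
    score = 1.0 - abs(value - stats_.best) / span
    return float(np.clip(score, 0.0, 1.0))


@dataclass
class BVSReport:
    """Scores for one participant against one normative database."""

    points: dict[str, int] = field(default_factory=dict)  # measure id -> 1..5
    subscores: dict[str, int] = field(default_factory=dict)  # A/B/C -> 0..10
    total: int | None = None  # 0..30; None if any component missing
    ebs: dict[str, float] = field(default_factory=dict)  # measure id -> [0,1]
    complete: bool = True
    missing: list[str] = field(default_factory=list)
    normative_source: str = ""

    def to_dict(self) -> dict:
        return {
            "points": self.points,
            "subscores": self.subscores,
            "total": self.total,
            "ebs": self.ebs,
            "complete": self.complete,
            "missing": self.missing,
            "normative_source": self.normative_source,
        }

    def text_block(self) -> str:
        lines = []
        for sub, comp in _COMPONENT_OF_SUBSCORE.items():
            lines.append(f"  {sub} ({comp}): {self.subscores.get(sub, '–')}/10")
        lines.append(f"  Total: {self.total if self.total is not None else '–'}/30")
        for mid in MEASURE_IDS:
            if mid in self.ebs:
                lines.append(f"  EBS {mid}: {self.ebs[mid]:.3f}")
        return "\n".join(lines)


def total_bvs(measure_values: dict[str, float], normative_db: dict) -> BVSReport:
    """Score the six measures into the A/B/C sub-scores and total /30.

    ``measure_values`` maps measure ids to scalar values; missing ids
    yield a partial report (``complete=False``, no total).
    """
    stats_map: dict[str, NormativeStats] = normative_db["measures"]
    report = BVSReport(normative_source=normative_db.get("source", ""))
    for mid in MEASURE_IDS:
        if mid not in measure_values:
            report.missing.append(mid)
            continue
        component, kind = mid.split("_")
        st = stats_map[mid]
        report.points[mid] = measure_points(measure_values[mid], st, kind, component)
        report.ebs[mid] = ebs(measure_values[mid], st)
    report.complete = not report.missing
    if report.complete:
        for sub, comp in _COMPONENT_OF_SUBSCORE.items():
            report.subscores[sub] = (
                report.points[f"{comp}_amplitude"] + report.points[f"{comp}_latency"]
            )
        report.total = sum(report.subscores.values())
    return report


def compare_groups_from_summaries(
    m1: float, s1: float, n1: int, m2: float, s2: float, n2: int
) -> tuple[float, int, float]:
    """Pooled two-sample t-test from printed summary statistics.

    Returns (t, df, two-tailed p) with df = n1 + n2 - 2. Useful for
    re-deriving significance from published group tables.
    """
    if s1 <= 0 or s2 <= 0:
        raise ValueError("SDs must be > 0")
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / df
    se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    t = (m1 - m2) / se
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), int(df), float(p)


def compare_groups(values1, values2, alpha: float = 0.05) -> tuple[float, float, str]:
    """Two-group comparison with a normality gate.

    Shapiro-Wilk on each sample at ``alpha``; if both pass, a two-tailed
    independent-samples t-test, otherwise the Wilcoxon rank-sum test.
    Returns (statistic, p, test name).
    """
    a = np.asarray(values1, dtype=float)
    b = np.asarray(values2, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("need n >= 3 per group")
    normal = all(stats.shapiro(x).pvalue > alpha for x in (a, b))
    if normal:
        res = stats.ttest_ind(a, b)
        return float(res.statistic), float(res.pvalue), "t-test"
    res = stats.ranksums(a, b)
    return float(res.statistic), float(res.pvalue), "rank-sum"
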