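"""Circle-of-Willis variant classification, NASCET stenosis grading, and
matched-group prevalence statistics.

Classification rules
--------------------
A ring segment is a *variation* when it is not visualized on angiography, or
when its diameter is more than 70 % thinner than the contralateral homologue
(the operational definition that covers both absence and hypoplasia). The
anterior communicating artery is exempt when the bilateral anterior cerebral
arteries are fused. The anterior part of the circle is complete when Aco and
both A1 are normal; the posterior part when both Pco and both P1 are normal;
the entire circle when both parts are complete.

Group comparisons
-----------------
Published prevalence tables print only (n, %) per group. Counts are
reconstructed by nearest-integer rounding of n x pct / 100 and compared with
Pearson's chi-square test on the 2x2 table, *without* Yates continuity
correction and without multiple-comparison adjustment, two-sided, df = 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .phantom import (CONTRALATERAL, COW_RING_SEGMENTS, CoWConfiguration,
                      Phantom, VesselSegment)
from .volume import Volume

# ---------------------------------------------------------------------------
# Per-segment classification


def classify_segment(diameter: float | None, contralateral_diameter: float | None,
                     visualized: bool, fused: bool = False) -> str:
    """Classify one ring segment as ``"normal"`` or ``"variation"``.

    ``fused=True`` encodes the fused-bilateral-ACA exception for Aco: the
    segment counts as normal even when not separately visualized.
    """
    if diameter is not None and diameter < 0:
        raise ValueError("diameter must be nonnegative")
    if contralateral_diameter is not None and contralateral_diameter < 0:
        raise ValueError("contralateral diameter must be nonnegative")
    if fused:
        return "normal"
    if not visualized:
        return "variation"
    if contralateral_diameter is not None and diameter is not None:
        if diameter < 0.3 * contralateral_diameter:  # "over 70 % thinner"
            return "variation"
    return "normal"


def classify_completeness(cfg: CoWConfiguration) -> tuple[bool, bool, bool]:
    """(entire, anterior, posterior) completeness flags.

    Anterior part: Aco + both A1; posterior part: both Pco + both P1.
    """
    s = cfg.statuses
    anterior = all(s[n] == "normal" for n in ("Aco", "A1_L", "A1_R"))
    posterior = all(s[n] == "normal" for n in ("Pco_L", "Pco_R", "P1_L", "P1_R"))
    return anterior and posterior, anterior, posterior


def classify_tree(tree: list[VesselSegment], aco_fused: bool = False) -> CoWConfiguration:
    """Apply the diameter/visualization rules to a ground-truth vessel tree."""
    by_name = {s.name: s for s in tree}
    statuses = {}
    for name in COW_RING_SEGMENTS:
        seg = by_name[name]
        visualized = seg.status != "absent"
        diameter = 2.0 * float(np.median(seg.radius_profile)) if visualized else None
        contra_d = None
        contra_name = CONTRALATERAL.get(name)
        if contra_name is not None:
            contra = by_name[contra_name]
            if contra.status != "absent":
                contra_d = 2.0 * float(np.median(contra.radius_profile))
        statuses[name] = classify_segment(diameter, contra_d, visualized,
                                          fused=aco_fused and name == "Aco")
    return CoWConfiguration(statuses, aco_fused)


def classify_phantom(phantom: Phantom) -> CoWConfiguration:
    """Classify a phantom from its ground-truth tree."""
    return classify_tree(phantom.tree, phantom.config.aco_fused_flag)


# ---------------------------------------------------------------------------
# Stenosis grading and measurement

_GRADE_BANDS = ("normal", "mild", "moderate", "severe")


@dataclass
class StenosisGrade:
    pct: float
    grade: str


def grade_stenosis(pct: float) -> StenosisGrade:
    """NASCET grade: normal (0), mild (<=29 %), moderate (30-69 %),
    severe (>=70 %). Fractional values between bands round to the nearest
    integer percentage first."""
    if not (0.0 <= pct <= 100.0):
        raise ValueError("stenosis percentage outside [0, 100]")
    p = pct
    if 29.0 < p < 30.0:
        p = round(p)
    if p == 0:
        grade = "normal"
    elif p <= 29.0:
        grade = "mild"
    elif p < 70.0:
        grade = "moderate"
    else:
        grade = "severe"
    return StenosisGrade(pct, grade)


def measure_stenosis_pct(mask: Volume, segment: VesselSegment,
                         n_stations: int = 80) -> float:
    """NASCET-style percent stenosis along a segment from a binary lumen mask.

    The local lumen diameter at stations along the centerline is taken as
    twice the inscribed-sphere radius, i.e. the Euclidean distance transform
    of the mask interpolated at the centerline point. For a circular lumen
    this equals the perpendicular cross-section diameter while remaining
    robust to centerline curvature and to oblique cuts near junctions, which
    bias plane-sampled areas on voxelized masks. The reference "normal"
    diameter is the median over all stations (the focal dip occupies a small
    fraction of the segment, so the median tracks the nominal caliber as a
    distal reference does, without being contaminated by the junction ends);
    the result is 100 * (1 - min diameter / reference), clipped to [0, 100].
    A lumen absent at any station yields a local diameter of 0, so a full
    occlusion — or an entirely empty mask — returns 100.
    """
    if segment.status == "absent":
        raise ValueError("cannot measure stenosis of an absent segment")
    edt = ndimage.distance_transform_edt(mask.data.astype(bool),
                                         sampling=mask.spacing_mm)
    cl = segment.centerline
    idx = (np.linspace(0.05, 0.95, n_stations) * (len(cl) - 1)).astype(int)
    vox = mask.world_to_voxel(cl[idx]).T
    diams = 2.0 * ndimage.map_coordinates(edt, vox, order=1, mode="constant")
    ref = float(np.median(diams))
    if ref <= 0:
        return 100.0
    return float(np.clip(100.0 * (1.0 - float(diams.min()) / ref), 0.0, 100.0))


# ---------------------------------------------------------------------------
# Group summaries and contingency statistics


@dataclass
class GroupSummary:
    """One prevalence-table row: group size and percent prevalence per outcome."""

    name: str
    n: int
    prevalence_pct: dict[str, float] = field(default_factory=dict)
    age_mean: float | None = None
    age_sd: float | None = None

    def __post_init__(self):
        if self.n <= 0:
            raise ValueError("group size must be positive")
        for k, p in self.prevalence_pct.items():
            if not (0.0 <= p <= 100.0):
                raise ValueError(f"prevalence {p} for {k!r} outside [0, 100]")


@dataclass
class ContingencyTable:
    """2x2 counts: rows = groups, columns = (event, non-event)."""

    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (2, 2):
            raise ValueError("contingency table must be 2x2")
        if np.any(self.counts < 0) or not np.issubdtype(self.counts.dtype, np.integer):
            raise ValueError("counts must be nonnegative integers")


def reconstruct_counts(n: int, pct: float) -> int:
    """Invert a printed (n, %) summary to an event count by nearest-integer
    rounding; warns when the count does not round-trip to the printed percent."""
    if not (0.0 <= pct <= 100.0):
        raise ValueError("percentage outside [0, 100]")

    def _half_up(x: float) -> int:
        return int(np.floor(x + 0.5))

    count = _half_up(n * pct / 100.0)
    if _half_up(100.0 * count / n) != _half_up(pct):
        warnings.warn(
            f"count {count}/{n} re-rounds to {_half_up(100.0 * count / n)}%, "
            f"not the printed {pct}%", stacklevel=2)
    return count


def chi_square_test(table: ContingencyTable | np.ndarray) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table, df = 1, two-sided, no continuity
    correction, no multiplicity adjustment."""
    t = table.counts if isinstance(table, ContingencyTable) else np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("need a 2x2 table")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("chi-square statistic undefined: zero margin")
    chi2, p, _, _ = stats.chi2_contingency(t, correction=False)
    return float(chi2), float(p)


def t_test_two_sample(mean1: float, sd1: float, n1: int,
                      mean2: float, sd2: float, n2: int,
                      welch: bool = False) -> tuple[float, float]:
    """Two-sided two-sample t-test from summary statistics (pooled variance by
    default, Welch optionally)."""
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be nonnegative")
    if sd1 == 0 and sd2 == 0:
        if mean1 == mean2:
            return 0.0, 1.0
        raise ValueError("degenerate: zero variance with unequal means")
    res = stats.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2,
                                     equal_var=not welch)
    return float(res.statistic), float(res.pvalue)


def compare_groups(rows: list[GroupSummary], outcomes: list[str],
                   pairs: list[tuple[str, str]], alpha: float = 0.05) -> pd.DataFrame:
    """Chi-square comparison of reconstructed counts for each (pair, outcome).

    Returns a table with columns (group1, group2, outcome, count1, n1, count2,
    n2, chi2, df, p, significant).
    """
    by_name = {r.name: r for r in rows}
    records = []
    for g1, g2 in pairs:
        if g1 not in by_name or g2 not in by_name:
            missing = g1 if g1 not in by_name else g2
            raise KeyError(f"group {missing!r} not found in summaries")
        r1, r2 = by_name[g1], by_name[g2]
        for outcome in outcomes:
            c1 = reconstruct_counts(r1.n, r1.prevalence_pct[outcome])
            c2 = reconstruct_counts(r2.n, r2.prevalence_pct[outcome])
            table = np.array([[c1, r1.n - c1], [c2, r2.n - c2]])
            if g1 == g2:
                chi2, p = 0.0, 1.0
            else:
                chi2, p = chi_square_test(table)
            records.append(dict(group1=g1, group2=g2, outcome=outcome,
                                count1=c1, n1=r1.n, count2=c2, n2=r2.n,
                                chi2=chi2, df=1, p=p, significant=p < alpha))
    return pd.DataFrame.from_records(records)


# ---------------------------------------------------------------------------
# Prevalence from phantom cohorts

_TABLE_OUTCOMES = ("Aco", "A1", "Pco", "P1", "entirety_incomplete",
                   "anterior_incomplete", "posterior_incomplete")


def cohort_prevalence(cohort, per_patient: bool = True) -> dict[str, float]:
    """Percent prevalence of variation per segment family and of incompleteness.

    ``cohort`` items may be Phantom objects, ground-truth trees (lists of
    VesselSegment), or already-classified CoWConfiguration objects. Bilateral
    families (A1, Pco, P1) count per patient as "variation on either side"
    when ``per_patient`` (the reporting convention of published prevalence
    tables); with ``per_patient=False`` each side counts separately.
    """
    n = len(cohort)
    if n == 0:
        raise ValueError("empty cohort")
    acc = {k: 0.0 for k in _TABLE_OUTCOMES}
    for item in cohort:
        if isinstance(item, CoWConfiguration):
            cfg = item
        elif isinstance(item, Phantom):
            cfg = classify_phantom(item)
        else:
            cfg = classify_tree(item)
        s = cfg.statuses
        acc["Aco"] += s["Aco"] == "variation"
        for fam in ("A1", "Pco", "P1"):
            lv = s[fam + "_L"] == "variation"
            rv = s[fam + "_R"] == "variation"
            acc[fam] += (lv or rv) if per_patient else 0.5 * (lv + rv)
        entire, anterior, posterior = classify_completeness(cfg)
        acc["entirety_incomplete"] += not entire
        acc["anterior_incomplete"] += not anterior
        acc["posterior_incomplete"] += not posterior
    return {k: 100.0 * v / n for k, v in acc.items()}


# ---------------------------------------------------------------------------
# Packaged group-summary table (published prevalence rows) and its comparisons


def load_group_summaries(path: str | None = None) -> list[GroupSummary]:
    """Load group summaries from CSV (default: the packaged prevalence table
    of the six age/sex/stenosis-matched patient groups)."""
    if path is None:
        ref = resources.files("cowseg.data") / "cow_group_summaries.csv"
        with resources.as_file(ref) as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(path)
    outcome_cols = [c for c in df.columns
                    if c not in ("group", "n", "age_mean", "age_sd", "male_pct")]
    rows = []
    for _, r in df.iterrows():
        rows.append(GroupSummary(
            name=r["group"], n=int(r["n"]),
            prevalence_pct={c: float(r[c]) for c in outcome_cols},
            age_mean=float(r["age_mean"]), age_sd=float(r["age_sd"])))
    return rows


#: the published matched-pair comparisons and the outcomes they flagged
STANDARD_COMPARISONS = [
    ("Yn", "Sn", "Aco"),
    ("Yn", "Sn", "anterior_incomplete"),
    ("Male", "Female", "Aco"),
    ("Male", "Female", "anterior_incomplete"),
    ("ESs", "Ec", "P1"),
    ("ESs", "Ec", "posterior_incomplete"),
]


def standard_comparison_table(rows: list[GroupSummary] | None = None) -> pd.DataFrame:
    """Run the six published matched-group comparisons on a summary table."""
    rows = rows if rows is not None else load_group_summaries()
    frames = []
    for g1, g2, outcome in STANDARD_COMPARISONS:
        frames.append(compare_groups(rows, [outcome], [(g1, g2)]))
    return pd.concat(frames, ignore_index=True)
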