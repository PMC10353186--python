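"""Patient–cohort fit scoring, star-plot data, and population-gap queries.

**Fit scoring.**  A patient is compared to a study arm feature by feature.
For a numeric feature the arm's summary statistic defines a band: mean ± k·SD
(k configurable, default 1), the interquartile range [q1, q3], or a reported
range [low, high]; an explicit eligibility age range on the study takes
precedence over the summary band for age.  The patient is *in range* iff the
value falls inside the band.  For a categorical feature the patient is in
range iff their category has nonzero count or percent in the arm.  The fit
score is the fraction of evaluated features in range; features the arm does
not summarize comparably are skipped and reported, never silently dropped.

**Star plots.**  Each evaluated feature becomes one radial axis; the patient
value and the arm band are min–max normalized per axis to [0, 1], and axes
are evenly spaced in input order — the visual of a patient polyline inside
(or escaping) the cohort band.

**Gap queries.**  Three corpus-level scenarios over assembled studies:
``study_match`` (studies satisfying all feature filters, e.g. nonzero
representation of a subgroup), ``study_limitation`` (arms where a subgroup is
absent or under-represented below a percent threshold), and
``study_quality`` (total cohort size ≥ a threshold with at least one arm
holding ≥ a given fraction of the total — the size-ratio reading of a "good
treatment to effect ratio").  Each answer carries the percentage of the
corpus it represents.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .cohorts import CharacteristicSummary, CohortModel, StatValue, TermLexicon, fold_label
from .errors import ValidationError, VocabularyError
from .staging import PatientRecord

GAP_SCENARIOS = ("study_match", "study_limitation", "study_quality")
FILTER_OPS = ("present", "absent", "ge", "le", "eq")

DEFAULT_SD_MULTIPLIER = 1.0
DEFAULT_REPRESENTATION_THRESHOLD = 5.0  # percent


@dataclass(frozen=True)
class FeatureFit:
    feature: str
    patient_value: float | str
    arm_center: float | None
    arm_low: float | None
    arm_high: float | None
    in_range: bool


@dataclass(frozen=True)
class FitReport:
    patient_id: str
    study_id: str
    arm_name: str
    features: tuple[FeatureFit, ...]
    skipped: tuple[str, ...]

    @property
    def evaluated_n(self) -> int:
        return len(self.features)

    @property
    def fit_score(self) -> float:
        if not self.features:
            return 0.0
        return sum(1 for f in self.features if f.in_range) / len(self.features)

    def to_dict(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "study_id": self.study_id,
            "arm_name": self.arm_name,
            "fit_score": self.fit_score,
            "evaluated_n": self.evaluated_n,
            "skipped": list(self.skipped),
            "features": [
                {
                    "feature": f.feature,
                    "patient_value": f.patient_value,
                    "arm_center": f.arm_center,
                    "arm_low": f.arm_low,
                    "arm_high": f.arm_high,
                    "in_range": f.in_range,
                }
                for f in self.features
            ],
        }


def _numeric(value) -> float | None:
    if isinstance(value, bool):
        return None
    if isinstance(value, (int, float)):
        return float(value) if math.isfinite(float(value)) else None
    try:
        return float(str(value))
    except (TypeError, ValueError):
        return None


def numeric_band(
    stat: StatValue, sd_multiplier: float = DEFAULT_SD_MULTIPLIER
) -> tuple[float, float, float] | None:
    """(center, low, high) summary band for a numeric statistic, or None when
    the statistic carries no dispersion to compare against."""
    if stat.kind == "mean_sd":
        mean, sd = stat.values["mean"], stat.values["sd"]
        return mean, mean - sd_multiplier * sd, mean + sd_multiplier * sd
    if stat.kind == "median_iqr":
        return stat.values["median"], stat.values["q1"], stat.values["q3"]
    if stat.kind == "median_range":
        return stat.values["median"], stat.values["low"], stat.values["high"]
    return None


def fit_patient(
    patient: PatientRecord | Mapping,
    model: CohortModel,
    arm_name: str,
    features: Sequence[str],
    sd_multiplier: float = DEFAULT_SD_MULTIPLIER,
    lexicon: TermLexicon | None = None,
) -> FitReport:
    """Score one patient against one study arm on the requested features.

    ``features`` are lexicon codes (or folded labels for unmatched
    characteristics).  Numeric patient values are compared against the arm's
    band; string values are treated as categorical and checked for nonzero
    representation.  Features with no comparable arm statistic — and patient
    features with no value — land in ``skipped``.
    """
    if isinstance(patient, PatientRecord):
        patient_id = patient.record_id
        values = dict(patient.features)
    else:
        values = dict(patient)
        patient_id = str(values.pop("record_id", values.pop("patient_id", "patient")))

    arm_stats = model.arm_stats(arm_name)

    def _comparable(code: str) -> bool:
        if code in arm_stats:
            return True
        raw = values.get(code)
        return isinstance(raw, str) and _category_stat(model, arm_name, raw, lexicon) is not None

    if not any(_comparable(code) for code in features):
        raise ValidationError(
            f"arm {arm_name!r} of study {model.study_id!r} summarizes none of "
            f"the requested features {list(features)}"
        )

    fits: list[FeatureFit] = []
    skipped: list[str] = []
    for code in features:
        raw = values.get(code)
        if raw is None or (isinstance(raw, str) and not raw.strip()):
            skipped.append(code)
            continue
        number = _numeric(raw)
        if number is not None:
            entry = arm_stats.get(code)
            band = numeric_band(entry[1], sd_multiplier) if entry else None
            if band is not None and code == "age" and model.eligibility:
                band = _eligibility_band(band, model.eligibility)
            elif band is None and code == "age" and model.eligibility:
                low, high = _eligibility_bounds(model.eligibility)
                if low is not None or high is not None:
                    lo = low if low is not None else -math.inf
                    hi = high if high is not None else math.inf
                    band = ((lo + hi) / 2 if math.isfinite(lo + hi) else number, lo, hi)
            if band is None:
                skipped.append(code)
                continue
            center, low, high = band
            fits.append(
                FeatureFit(
                    feature=code,
                    patient_value=number,
                    arm_center=center,
                    arm_low=low,
                    arm_high=high,
                    in_range=low <= number <= high,
                )
            )
        else:
            category = str(raw)
            stat = _category_stat(model, arm_name, category, lexicon)
            if stat is None:
                skipped.append(code)
                continue
            fits.append(
                FeatureFit(
                    feature=code,
                    patient_value=category,
                    arm_center=stat.get("percent"),
                    arm_low=None,
                    arm_high=None,
                    in_range=_represented(stat),
                )
            )
    return FitReport(
        patient_id=patient_id,
        study_id=model.study_id,
        arm_name=arm_name,
        features=tuple(fits),
        skipped=tuple(skipped),
    )


def _eligibility_bounds(eligibility: Mapping) -> tuple[float | None, float | None]:
    return (_numeric(eligibility.get("age_min")), _numeric(eligibility.get("age_max")))


def _eligibility_band(
    band: tuple[float, float, float], eligibility: Mapping
) -> tuple[float, float, float]:
    """Eligibility age limits take precedence over the summary band."""
    center, low, high = band
    e_low, e_high = _eligibility_bounds(eligibility)
    return center, (e_low if e_low is not None else low), (e_high if e_high is not None else high)


def _category_stat(
    model: CohortModel, arm_name: str, category: str | None,
    lexicon: TermLexicon | None = None,
) -> StatValue | None:
    if not category:
        return None
    folded = fold_label(category)
    code = None
    if lexicon is not None:
        entry = lexicon.lookup(category)
        code = entry.code if entry else None
    for char in model.characteristics:
        if arm_name not in char.stats:
            continue
        keys = {fold_label(char.name)}
        if char.normalized.matched:
            keys.add(char.normalized.code)
        if folded in keys or (code is not None and code in keys) or category in keys:
            return char.stats[arm_name]
    return None


def _represented(stat: StatValue) -> bool:
    count = stat.get("count")
    percent = stat.get("percent")
    if count is None and percent is None:
        return False
    return (count or 0) > 0 or (percent or 0) > 0


@dataclass(frozen=True)
class StarPlotData:
    features: tuple[str, ...]
    angles_deg: tuple[float, ...]
    patient: tuple[float, ...]
    band_low: tuple[float, ...]
    band_high: tuple[float, ...]


def star_plot_data(report: FitReport) -> StarPlotData:
    """Radial coordinates for the patient polyline and the arm band.

    Requires ≥3 evaluated features (a polygon).  Each axis is min–max
    normalized over {patient value, band low, band high}; categorical
    features map representation to 1.0 in / 0.0 out with a full band.
    """
    if report.evaluated_n < 3:
        raise ValidationError(
            f"star plot needs ≥3 evaluated features, got {report.evaluated_n}"
        )
    n = report.evaluated_n
    angles = tuple(360.0 * i / n for i in range(n))
    patient, low, high = [], [], []
    for f in report.features:
        number = _numeric(f.patient_value)
        if number is None or f.arm_low is None or f.arm_high is None:
            patient.append(1.0 if f.in_range else 0.0)
            low.append(0.0)
            high.append(1.0)
            continue
        lo = min(number, f.arm_low, f.arm_high)
        hi = max(number, f.arm_low, f.arm_high)
        span = hi - lo
        if span == 0:
            patient.append(0.5)
            low.append(0.5)
            high.append(0.5)
        else:
            patient.append((number - lo) / span)
            low.append((f.arm_low - lo) / span)
            high.append((f.arm_high - lo) / span)
    return StarPlotData(
        features=tuple(f.feature for f in report.features),
        angles_deg=angles,
        patient=tuple(patient),
        band_low=tuple(low),
        band_high=tuple(high),
    )


def plot_star(data: StarPlotData, path: str, title: str = "") -> None:
    """Render the star plot to an image file (patient polyline over the
    cohort band)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import numpy as np

    theta = np.radians(np.array(data.angles_deg + (data.angles_deg[0],)))

    def closed(seq):
        return np.array(seq + (seq[0],))

    fig, ax = plt.subplots(subplot_kw={"projection": "polar"}, figsize=(5, 5))
    ax.fill_between(theta, closed(data.band_low), closed(data.band_high),
                    color="red", alpha=0.25, label="arm band")
    ax.plot(theta, closed(data.patient), color="blue", marker="o", label="patient")
    ax.set_xticks(np.radians(np.array(data.angles_deg)))
    ax.set_xticklabels(data.features)
    ax.set_ylim(0, 1.05)
    if title:
        ax.set_title(title)
    ax.legend(loc="lower right", bbox_to_anchor=(1.1, -0.1))
    fig.savefig(path, bbox_inches="tight")
    plt.close(fig)


@dataclass(frozen=True)
class GapFilter:
    feature: str
    op: str
    value: float | str | None = None

    def __post_init__(self) -> None:
        if self.op not in FILTER_OPS:
            raise VocabularyError(f"unknown filter op {self.op!r}; expected {FILTER_OPS}")


@dataclass(frozen=True)
class GapQuerySpec:
    scenario: str
    filters: tuple[GapFilter, ...] = ()
    size_threshold: int = 1000
    arm_fraction: float = 1.0 / 3.0
    representation_threshold: float = DEFAULT_REPRESENTATION_THRESHOLD

    def __post_init__(self) -> None:
        if self.scenario not in GAP_SCENARIOS:
            raise VocabularyError(
                f"unknown scenario {self.scenario!r}; expected {GAP_SCENARIOS}"
            )
        if self.scenario in ("study_match", "study_limitation") and not self.filters:
            raise ValidationError(f"{self.scenario} requires at least one filter")

    @classmethod
    def from_dict(cls, payload: Mapping) -> "GapQuerySpec":
        filters = tuple(
            GapFilter(f["feature"], f["op"], f.get("value"))
            for f in payload.get("filters", ())
        )
        return cls(
            scenario=payload["scenario"],
            filters=filters,
            size_threshold=int(payload.get("size_threshold", 1000)),
            arm_fraction=float(payload.get("arm_fraction", 1.0 / 3.0)),
            representation_threshold=float(
                payload.get("representation_threshold", DEFAULT_REPRESENTATION_THRESHOLD)
            ),
        )

    def to_dict(self) -> dict:
        return {
            "scenario": self.scenario,
            "filters": [
                {"feature": f.feature, "op": f.op, "value": f.value} for f in self.filters
            ],
            "size_threshold": self.size_threshold,
            "arm_fraction": self.arm_fraction,
            "representation_threshold": self.representation_threshold,
        }


@dataclass(frozen=True)
class GapQueryResult:
    spec: GapQuerySpec
    matches: tuple[str, ...]  # study ids, or "study/arm" for limitation
    percentage: float  # matched studies / corpus size, in percent

    def to_dict(self) -> dict:
        return {
            "spec": self.spec.to_dict(),
            "matches": list(self.matches),
            "percentage": self.percentage,
        }


def _validate_filter_features(spec: GapQuerySpec, lexicon: TermLexicon | None) -> None:
    if lexicon is None:
        return
    known = {e.code for e in lexicon.entries.values()}
    for flt in spec.filters:
        if flt.feature not in known and fold_label(flt.feature) not in lexicon.entries:
            raise VocabularyError(f"unknown feature code {flt.feature!r} in filter")


def _study_feature_stats(model: CohortModel, feature: str) -> list[StatValue]:
    """All per-arm statistics for a feature code across a study."""
    out = []
    for arm in model.arms:
        entry = model.arm_stats(arm.arm_name).get(feature)
        if entry is not None:
            out.append(entry[1])
    return out


def _arm_feature_stat(model: CohortModel, arm_name: str, feature: str) -> StatValue | None:
    entry = model.arm_stats(arm_name).get(feature)
    return entry[1] if entry else None


def _central_value(stat: StatValue) -> float | None:
    for key in ("mean", "median", "value", "percent", "count"):
        v = stat.get(key)
        if v is not None:
            return v
    return None


def _filter_matches_study(model: CohortModel, flt: GapFilter) -> bool:
    stats = _study_feature_stats(model, flt.feature)
    if flt.op == "present":
        return any(_represented(s) or _central_value(s) is not None for s in stats)
    if flt.op == "absent":
        return not any(_represented(s) or _central_value(s) is not None for s in stats)
    target = _numeric(flt.value)
    if target is None:
        raise ValidationError(f"filter {flt.feature!r} op {flt.op!r} needs a numeric value")
    centers = [c for c in (_central_value(s) for s in stats) if c is not None]
    if not centers:
        return False
    if flt.op == "ge":
        return any(c >= target for c in centers)
    if flt.op == "le":
        return any(c <= target for c in centers)
    return any(c == target for c in centers)


def run_gap_query(
    corpus: Sequence[CohortModel],
    spec: GapQuerySpec,
    lexicon: TermLexicon | None = None,
) -> GapQueryResult:
    """Run one gap-identification scenario over an assembled corpus.

    Returns the matching studies (or ``study/arm`` pairs for limitation
    scenarios) and the percentage of the corpus they represent.
    """
    if not corpus:
        raise ValidationError("empty corpus")
    _validate_filter_features(spec, lexicon)

    matches: list[str] = []
    matched_studies: set[str] = set()
    for model in corpus:
        if spec.scenario == "study_match":
            if all(_filter_matches_study(model, f) for f in spec.filters):
                matches.append(model.study_id)
                matched_studies.add(model.study_id)
        elif spec.scenario == "study_limitation":
            for arm in model.arms:
                if all(
                    _subgroup_missing_in_arm(model, arm.arm_name, f, spec)
                    for f in spec.filters
                ):
                    matches.append(f"{model.study_id}/{arm.arm_name}")
                    matched_studies.add(model.study_id)
        else:  # study_quality
            total = model.total_size
            if total >= spec.size_threshold and any(
                arm.size >= spec.arm_fraction * total for arm in model.arms
            ):
                if all(_filter_matches_study(model, f) for f in spec.filters):
                    matches.append(model.study_id)
                    matched_studies.add(model.study_id)
    percentage = 100.0 * len(matched_studies) / len(corpus)
    return GapQueryResult(spec=spec, matches=tuple(matches), percentage=percentage)


def _subgroup_missing_in_arm(
    model: CohortModel, arm_name: str, flt: GapFilter, spec: GapQuerySpec
) -> bool:
    """Limitation semantics: the subgroup is absent from the arm or its
    percent is below the representation threshold."""
    stat = _arm_feature_stat(model, arm_name, flt.feature)
    if stat is None or not _represented(stat):
        return True
    percent = stat.get("percent")
    return percent is not None and percent < spec.representation_threshold


def corpus_summary(
    corpus: Sequence[CohortModel],
    specs: Iterable[GapQuerySpec],
    lexicon: TermLexicon | None = None,
):
    """One row per query spec: scenario, match count, corpus percentage."""
    import pandas as pd

    rows = []
    for spec in specs:
        result = run_gap_query(corpus, spec, lexicon=lexicon)
        rows.append(
            {
                "scenario": spec.scenario,
                "filters": "; ".join(
                    f"{f.feature} {f.op}" + (f" {f.value}" if f.value is not None else "")
                    for f in spec.filters
                ),
                "n_matches": len({m.split("/")[0] for m in result.matches}),
                "percentage": result.percentage,
            }
        )
    return pd.DataFrame(rows, columns=["scenario", "filters", "n_matches", "percentage"])
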