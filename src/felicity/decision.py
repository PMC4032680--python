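"""Happiness classification from the per-measure statistical batteries.

The model locates happiness in a three-dimensional affect space: high
physiological arousal, positive emotional valence, and high life
satisfaction.  Each dimension carries several physiological indexes with an
expected pairwise-significance pattern over the (relax, happiness, stress)
epochs:

* arousal - candidate differs from relax, resembles stress (HR, SC, beta
  power, pupil size up; respiration depth down);
* valence - candidate resembles relax, differs from stress (zygomatic EMG and
  frontal alpha asymmetry up; corrugator EMG and startle down);
* satisfaction - candidate differs from both ground truths, sitting at the
  vagally-dominant extreme (NN50, RMSSD, HF power up; LF/HF, LF power down).

A dimension is supported when a strict majority of its measures meet their
pattern; happiness requires all three dimensions.  Arousal alone can never
yield happiness - the arousal profile of a happiness experience is
indistinguishable from stress by design, so an arousal-only match is
explicitly guarded against.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

from .cohort import EPOCH_LABELS, MEASURES
from .stats import (RmBattery, PowerSpec, PowerResult, achieved_power,
                    cohens_f_from_eta)

DIMENSIONS = ("arousal", "valence", "satisfaction")

#: strict-majority quorum: supported requires fraction > quorum
DEFAULT_QUORUM = 0.5

AROUSAL_GUARD_NOTE = (
    "arousal indexes are expected to resemble stress during a happiness "
    "experience; never classify happiness from physiological arousal alone"
)


class TrendClass(str, Enum):
    linear_only = "linear_only"
    both = "both"
    quadratic_only = "quadratic_only"
    neither = "neither"


@dataclass(frozen=True)
class MeasureSpec:
    """Expected behaviour of one index under the three-epoch protocol."""

    measure: str
    dimension: str
    direction: str                       # larger_is_higher | smaller_is_higher
    expected_sig: tuple[tuple[str, str], ...]
    expected_nonsig: tuple[tuple[str, str], ...]
    expected_extreme_epoch: str = "happiness"

    def __post_init__(self) -> None:
        if self.dimension not in DIMENSIONS:
            raise ValueError(f"unknown dimension {self.dimension!r}")
        if self.direction not in ("larger_is_higher", "smaller_is_higher"):
            raise ValueError(f"unknown direction {self.direction!r}")

    def adjust(self, value: float) -> float:
        """Map a raw index value onto the dimension-positive scale."""
        return value if self.direction == "larger_is_higher" else -value


_HR = (("relax", "happiness"),)
_HS = (("happiness", "stress"),)
_BOTH = _HR + _HS


def _spec(measure, dimension, direction, sig, nonsig):
    return MeasureSpec(measure, dimension, direction, sig, nonsig)


#: the 14 default measure expectations
DEFAULT_MEASURE_SPECS: tuple[MeasureSpec, ...] = (
    # arousal: candidate > relax, candidate ~ stress
    _spec("HR", "arousal", "larger_is_higher", _HR, _HS),
    _spec("SC", "arousal", "larger_is_higher", _HR, _HS),
    _spec("beta_power", "arousal", "larger_is_higher", _HR, _HS),
    _spec("pupil_size", "arousal", "larger_is_higher", _HR, _HS),
    _spec("rsp_depth", "arousal", "smaller_is_higher", _HR, _HS),
    # valence: candidate ~ relax, candidate > stress (dimension-positive)
    _spec("emg_zyg", "valence", "larger_is_higher", _HS, _HR),
    _spec("alpha_asym", "valence", "larger_is_higher", _HS, _HR),
    _spec("emg_corr", "valence", "smaller_is_higher", _HS, _HR),
    _spec("startle", "valence", "smaller_is_higher", _HS, _HR),
    # satisfaction: candidate differs from (exceeds) both ground truths
    _spec("nn50", "satisfaction", "larger_is_higher", _BOTH, ()),
    _spec("rmssd", "satisfaction", "larger_is_higher", _BOTH, ()),
    _spec("hf_power", "satisfaction", "larger_is_higher", _BOTH, ()),
    _spec("lf_hf", "satisfaction", "smaller_is_higher", _BOTH, ()),
    _spec("lf_power", "satisfaction", "smaller_is_higher", _BOTH, ()),
)

SPEC_BY_MEASURE = {s.measure: s for s in DEFAULT_MEASURE_SPECS}
assert set(SPEC_BY_MEASURE) == set(MEASURES)


# ---------------------------------------------------------------------------
# Outcome containers
# ---------------------------------------------------------------------------

@dataclass
class MeasureOutcome:
    measure: str
    dimension: str
    pattern_met: bool
    direction_ok: bool
    trend: TrendClass
    main_effect_significant: bool
    contradicted: bool
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["trend"] = self.trend.value
        return d


@dataclass
class DimensionVerdict:
    dimension: str
    supported: bool
    support_fraction: float
    outcomes: list[MeasureOutcome]
    contradicted: bool
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {"dimension": self.dimension, "supported": self.supported,
                "support_fraction": self.support_fraction,
                "contradicted": self.contradicted, "notes": self.notes,
                "outcomes": [o.to_dict() for o in self.outcomes]}


@dataclass
class HappinessReport:
    classification: str          # happiness | not_happiness | inconclusive
    verdicts: dict[str, DimensionVerdict]
    guard_notes: list[str]
    power_diagnostics: Optional[dict] = None

    def to_dict(self) -> dict:
        return {"classification": self.classification,
                "verdicts": {d: v.to_dict() for d, v in self.verdicts.items()},
                "guard_notes": self.guard_notes,
                "power_diagnostics": self.power_diagnostics}


# ---------------------------------------------------------------------------
# Classification logic
# ---------------------------------------------------------------------------

def classify_trend(linear_p: float, quadratic_p: float,
                   alpha: float = 0.05) -> TrendClass:
    """The three situations of significant polynomial contrasts (plus
    'neither' when no trend reaches significance)."""
    for name, p in (("linear_p", linear_p), ("quadratic_p", quadratic_p)):
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"{name} must be in [0, 1], got {p}")
    lin, quad = linear_p < alpha, quadratic_p < alpha
    if lin and quad:
        return TrendClass.both
    if lin:
        return TrendClass.linear_only
    if quad:
        return TrendClass.quadratic_only
    return TrendClass.neither


def _find_pair(battery: RmBattery, pair: tuple[str, str]):
    want = frozenset(pair)
    for pw in battery.pairwise:
        if frozenset(pw.pair) == want:
            return pw
    raise ValueError(f"pair {pair!r} not present in battery for "
                     f"{battery.measure!r}")


def evaluate_measure(spec: MeasureSpec, battery: RmBattery,
                     alpha: float = 0.05) -> MeasureOutcome:
    """Check one measure against its expected pattern.

    pattern_met requires: a significant (corrected) main effect; every
    expected-significant pair significant with the candidate epoch higher on
    the dimension-positive scale; every expected-similar pair non-significant;
    and a significant quadratic contrast oriented with the candidate epoch
    elevated (negative quadratic estimate after smaller-is-higher inversion).
    A quadratic-only trend strengthens the outcome and is annotated.
    """
    if spec.measure != battery.measure:
        raise ValueError(f"spec is for {spec.measure!r} but battery is for "
                         f"{battery.measure!r}")
    notes: list[str] = []
    means = {lab: spec.adjust(v) for lab, v in battery.epoch_means.items()}
    main_sig = battery.p_corrected < alpha

    direction_ok = True
    sig_ok = True
    contradicted = False
    for pair in spec.expected_sig:
        pw = _find_pair(battery, pair)
        other = pair[0] if pair[1] == "happiness" else pair[1]
        cand_higher = means["happiness"] > means[other]
        if not (pw.p_adjusted < alpha):
            sig_ok = False
        if not cand_higher:
            direction_ok = False
            if pw.p_adjusted < alpha:
                contradicted = True
                notes.append(f"significant {pair[0]}-vs-{pair[1]} difference "
                             f"in the direction opposite to the hypothesis")
    nonsig_ok = True
    for pair in spec.expected_nonsig:
        pw = _find_pair(battery, pair)
        if pw.p_adjusted < alpha:
            nonsig_ok = False

    ct = battery.contrasts
    trend = classify_trend(ct.linear_p, ct.quadratic_p, alpha)
    quad_est_adj = spec.adjust(ct.quadratic_estimate)
    # candidate epoch elevated relative to the endpoint average -> negative
    # quadratic component with (1, -2, 1) coefficients
    quad_ok = (ct.quadratic_p < alpha) and (quad_est_adj < 0)

    pattern_met = main_sig and sig_ok and nonsig_ok and direction_ok and quad_ok
    if pattern_met and trend is TrendClass.quadratic_only:
        notes.append("strengthened: quadratic-only trend (candidate epoch "
                     "dominates both ground truths)")
    return MeasureOutcome(measure=spec.measure, dimension=spec.dimension,
                          pattern_met=pattern_met, direction_ok=direction_ok,
                          trend=trend, main_effect_significant=main_sig,
                          contradicted=contradicted, notes=notes)


def evaluate_dimension(specs: Sequence[MeasureSpec],
                       batteries: dict[str, RmBattery],
                       alpha: float = 0.05,
                       quorum: float = DEFAULT_QUORUM) -> DimensionVerdict:
    """Aggregate a dimension's measures: supported iff the fraction of
    pattern-met measures strictly exceeds the quorum."""
    if not specs:
        raise ValueError("empty measure-spec list")
    dims = {s.dimension for s in specs}
    if len(dims) != 1:
        raise ValueError(f"specs span multiple dimensions: {sorted(dims)}")
    dimension = dims.pop()
    outcomes = [evaluate_measure(s, batteries[s.measure], alpha) for s in specs]
    n_met = sum(o.pattern_met for o in outcomes)
    frac = n_met / len(outcomes)
    supported = frac > quorum
    n_contra = sum(o.contradicted for o in outcomes)
    contradicted = n_contra / len(outcomes) > quorum
    notes = []
    if frac == quorum:
        notes.append(f"borderline: support fraction exactly at quorum "
                     f"({n_met}/{len(outcomes)}); strict-majority rule "
                     f"leaves the dimension unsupported")
    return DimensionVerdict(dimension=dimension, supported=supported,
                            support_fraction=frac, outcomes=outcomes,
                            contradicted=contradicted, notes=notes)


def _hr_consistency_note(verdicts: dict[str, DimensionVerdict]) -> Optional[str]:
    """Warn when HR disagrees with the other cardiovascular indexes
    (baroreflex / Mayer-wave interplay can depress HR at 0.1 Hz)."""
    arousal = verdicts.get("arousal")
    satisfaction = verdicts.get("satisfaction")
    if arousal is None or satisfaction is None:
        return None
    hr = next((o for o in arousal.outcomes if o.measure == "HR"), None)
    cardio = [o for o in satisfaction.outcomes
              if o.measure in ("lf_hf", "lf_power", "hf_power", "nn50", "rmssd")]
    if hr is None or not cardio:
        return None
    if not hr.direction_ok and any(o.pattern_met for o in cardio):
        return ("HR disagrees with the other cardiovascular indexes; inspect "
                "for baroreceptor-reflex / Mayer-wave cross-dimension "
                "contamination before trusting the arousal verdict")
    return None


def decide_happiness(verdicts: dict[str, DimensionVerdict],
                     power_diagnostics: Optional[dict] = None) -> HappinessReport:
    """Combine the three dimension verdicts into the final classification.

    happiness requires all three dimensions supported; an actively
    contradicted valence or satisfaction dimension - or both of them
    unsupported - yields not_happiness; anything else is inconclusive.
    """
    if set(verdicts) != set(DIMENSIONS):
        raise ValueError(f"need exactly one verdict per dimension "
                         f"{DIMENSIONS}, got {sorted(verdicts)}")
    guard_notes = [AROUSAL_GUARD_NOTE]
    note = _hr_consistency_note(verdicts)
    if note:
        guard_notes.append(note)

    v_a, v_v, v_s = (verdicts[d] for d in DIMENSIONS)
    if v_a.supported and v_v.supported and v_s.supported:
        cls = "happiness"
    elif v_v.contradicted or v_s.contradicted:
        cls = "not_happiness"
    elif not v_v.supported and not v_s.supported:
        cls = "not_happiness"
        if v_a.supported:
            guard_notes.append(
                "arousal is the only supported dimension; by the model's "
                "guard this pattern is indistinguishable from stress and is "
                "classified as not_happiness")
    else:
        cls = "inconclusive"
    return HappinessReport(classification=cls, verdicts=verdicts,
                           guard_notes=guard_notes,
                           power_diagnostics=power_diagnostics)


def classify(batteries: dict[str, RmBattery], alpha: float = 0.05,
             quorum: float = DEFAULT_QUORUM,
             specs: Sequence[MeasureSpec] = DEFAULT_MEASURE_SPECS,
             power_f: float = 0.25) -> HappinessReport:
    """Full decision stage: evaluate every dimension and classify.

    Power diagnostics report post hoc achieved power at the cohort's size for
    the conventional planning effect (f = 0.25) and for the weakest observed
    per-measure effect.
    """
    verdicts = {}
    for dim in DIMENSIONS:
        dim_specs = [s for s in specs if s.dimension == dim]
        verdicts[dim] = evaluate_dimension(dim_specs, batteries, alpha, quorum)

    n = next(iter(batteries.values())).n_subjects
    diagnostics = None
    try:
        planning = achieved_power(PowerSpec(f=power_f, alpha=alpha), n)
        f_obs = [cohens_f_from_eta(min(b.partial_eta_sq, 1 - 1e-12))
                 for b in batteries.values()]
        f_min = max(min(f_obs), 1e-6)
        weakest = achieved_power(PowerSpec(f=f_min, alpha=alpha), n)
        diagnostics = {"n_subjects": n,
                       "planning_f": power_f,
                       "planning": planning.to_dict(),
                       "weakest_measure_f": f_min,
                       "weakest_measure": weakest.to_dict()}
    except ValueError:
        diagnostics = None
    return decide_happiness(verdicts, power_diagnostics=diagnostics)


# ---------------------------------------------------------------------------
# Text report
# ---------------------------------------------------------------------------

def format_report(report: HappinessReport,
                  batteries: dict[str, RmBattery]) -> str:
    """Human-readable per-measure summary plus the classification."""
    lines = [f"classification: {report.classification}", ""]
    for dim, verdict in report.verdicts.items():
        lines.append(f"[{dim}]  supported={verdict.supported}  "
                     f"support={verdict.support_fraction:.2f}")
        for o in verdict.outcomes:
            b = batteries[o.measure]
            means = "  ".join(f"{lab}={v:.3g}"
                              for lab, v in b.epoch_means.items())
            lines.append(
                f"  {o.measure:<11} {means}")
            lines.append(
                f"    F({b.df1_corrected:.2f},{b.df2_corrected:.2f})="
                f"{b.F:.3f}  p_raw={b.p_uncorrected:.4g} "
                f"p_corr={b.p_corrected:.4g} ({b.correction_used}) "
                f"eps_gg={b.epsilon_gg:.3f} eta_p2={b.partial_eta_sq:.3f}")
            pws = "  ".join(
                f"{pw.pair[0][0].upper()}-{pw.pair[1][0].upper()} "
                f"p_adj={pw.p_adjusted:.4g}{'*' if pw.significant else ''}"
                for pw in b.pairwise)
            ct = b.contrasts
            lines.append(f"    pairwise: {pws}   contrasts: "
                         f"lin p={ct.linear_p:.4g} quad p={ct.quadratic_p:.4g} "
                         f"[{o.trend.value}]  pattern_met={o.pattern_met}")
            for note in o.notes:
                lines.append(f"    note: {note}")
        for note in verdict.notes:
            lines.append(f"  note: {note}")
        lines.append("")
    for note in report.guard_notes:
        lines.append(f"guard: {note}")
    if report.power_diagnostics:
        pd_ = report.power_diagnostics
        lines.append(
            f"power: n={pd_['n_subjects']}, planning f={pd_['planning_f']} -> "
            f"achieved {pd_['planning']['achieved_power']:.3f}; weakest "
            f"measure f={pd_['weakest_measure_f']:.3f} -> "
            f"{pd_['weakest_measure']['achieved_power']:.3f}")
    return "\n".join(lines)
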