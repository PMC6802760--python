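"""End-to-end analysis: trials -> profiles -> fits -> spans -> statistics.

The stages mirror how the experiment is analysed: per-position accuracy
profiles per participant and complexity, Gaussian/double-Gaussian fits with
deterministic model selection, span size at the criterion in characters and
in bits, a 2 x 3 mixed ANOVA with Bonferroni-corrected follow-up t-tests,
descriptive and inferential asymmetry summaries, fixation (position 0)
accuracy by trigram role, and — when reading records are supplied —
Pearson correlations between span and reading speed, pooled across and
within complexity levels.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import reading as reading_mod
from .design import (SessionDesign, build_profiles, center_role_accuracy,
                     default_design, profiles_to_frame)
from .errors import (DegenerateDesignError, IncompleteDesignError,
                     UndefinedCorrelationError)
from .spanfit import DEFAULT_CRITERION, estimate_span
from .stats import (AnovaResult, PairwiseResult, mixed_anova,
                    pairwise_age_by_complexity, pairwise_to_frame, pearson_r)

log = logging.getLogger(__name__)


@dataclass
class AnalysisResult:
    """All pipeline outputs for one trial (+ optional reading) dataset."""

    profiles: pd.DataFrame
    spans: pd.DataFrame
    anova_chars: AnovaResult
    anova_bits: AnovaResult
    pairwise_chars: list[PairwiseResult]
    pairwise_bits: list[PairwiseResult]
    center_role: pd.DataFrame
    asymmetry_summary: pd.DataFrame
    anova_asymmetry: AnovaResult | None = None
    speeds: pd.DataFrame | None = None
    correlations: pd.DataFrame | None = None

    def stats_dict(self) -> dict:
        """JSON-ready digest of every inferential result."""
        out = {
            "anova": {
                "span_chars": _anova_dict(self.anova_chars),
                "span_bits": _anova_dict(self.anova_bits),
            },
            "pairwise": {
                "span_chars": pairwise_to_frame(self.pairwise_chars).to_dict("records"),
                "span_bits": pairwise_to_frame(self.pairwise_bits).to_dict("records"),
            },
            "asymmetry": self.asymmetry_summary.to_dict("records"),
            "center_role_accuracy": self.center_role.to_dict("records"),
        }
        if self.anova_asymmetry is not None:
            out["anova"]["asymmetry"] = _anova_dict(self.anova_asymmetry)
        if self.correlations is not None:
            out["correlations"] = self.correlations.to_dict("records")
        return out


def _anova_dict(res: AnovaResult) -> dict:
    return {
        name: {"effect": e.effect, "F": e.F, "df_num": e.df[0],
               "df_den": e.df[1], "p": e.p,
               "partial_eta_sq": e.partial_eta_sq,
               "gg_epsilon": e.gg_epsilon}
        for name, e in res.effects.items()
    } | {"gg_corrected": res.gg_corrected}


def spans_from_trials(trials: pd.DataFrame,
                      design: SessionDesign | None = None,
                      criterion: float = DEFAULT_CRITERION,
                      delta_r2: float = 0.01) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Profiles and span estimates for every participant x complexity.

    Returns (profiles frame, spans frame); the spans frame keeps full
    precision (rounding to one decimal happens only when written out).
    """
    design = design or default_design()
    profiles = build_profiles(trials, design)
    log.info("built %d profiles", len(profiles))
    rows = []
    for prof in profiles:
        est, fit = estimate_span(prof, criterion=criterion, delta_r2=delta_r2,
                                 set_size=design.set_size)
        rows.append((prof.participant_id, prof.age_group, prof.complexity,
                     fit.model, est.span_chars, est.left_extent,
                     est.right_extent, est.asymmetry, est.span_bits,
                     est.criterion, fit.r_squared))
    spans = pd.DataFrame(rows, columns=[
        "participant_id", "age_group", "complexity", "model", "span_chars",
        "left_extent", "right_extent", "asymmetry", "span_bits", "criterion",
        "r_squared"])
    log.info("estimated %d spans (%d zero)", len(spans),
             int((spans["span_chars"] == 0).sum()))
    return profiles_to_frame(profiles), spans


def _correlations(spans: pd.DataFrame, speeds: pd.DataFrame) -> pd.DataFrame:
    rows = []
    pairings = [("participant_mean", None)]
    pairings += [("per_complexity", c) for c in
                 sorted(spans["complexity"].unique())]
    for pooling, comp in pairings:
        paired = reading_mod.span_speed_join(spans, speeds, pooling=pooling,
                                             complexity=comp)
        label = "all" if comp is None else comp
        try:
            r, p, n = pearson_r(paired["span"], paired["cpm"])
        except UndefinedCorrelationError as exc:
            log.warning("correlation undefined for %s: %s", label, exc)
            r, p, n = float("nan"), float("nan"), len(paired)
        rows.append((pooling, label, r, p, n))
    return pd.DataFrame(rows, columns=["pooling", "complexity", "r", "p", "n"])


def analyze(trials: pd.DataFrame,
            reading_records: pd.DataFrame | None = None,
            design: SessionDesign | None = None,
            criterion: float = DEFAULT_CRITERION,
            delta_r2: float = 0.01,
            gg_correct: bool = True,
            speed_mode: str = "mean_of_speeds") -> AnalysisResult:
    """Run the full analysis; see the module docstring for the stage list."""
    design = design or default_design()
    profiles_df, spans = spans_from_trials(trials, design, criterion, delta_r2)

    anova_chars = mixed_anova(spans, gg_correct=gg_correct, dv="span_chars")
    anova_bits = mixed_anova(spans, gg_correct=gg_correct, dv="span_bits")
    pw_chars = pairwise_age_by_complexity(spans, dv="span_chars")
    pw_bits = pairwise_age_by_complexity(spans, dv="span_bits")
    log.info("ANOVA (chars): %s", anova_chars.to_frame().to_dict("records"))

    # Asymmetry: descriptive by group/complexity; zero-span cells (NaN) are
    # excluded, and the inferential mixed ANOVA runs only on participants
    # with a defined asymmetry at every level.
    asym = spans.dropna(subset=["asymmetry"])
    asym_summary = (asym.groupby(["age_group", "complexity"])["asymmetry"]
                    .agg(["mean", "sem", "count"]).reset_index())
    anova_asym = None
    complete = (asym.groupby("participant_id")["complexity"].nunique()
                == spans["complexity"].nunique())
    keep = complete[complete].index
    sub = asym[asym["participant_id"].isin(keep)]
    try:
        anova_asym = mixed_anova(sub, gg_correct=gg_correct, dv="asymmetry")
    except (IncompleteDesignError, DegenerateDesignError) as exc:
        log.warning("asymmetry ANOVA skipped: %s", exc)

    result = AnalysisResult(
        profiles=profiles_df, spans=spans,
        anova_chars=anova_chars, anova_bits=anova_bits,
        pairwise_chars=pw_chars, pairwise_bits=pw_bits,
        center_role=center_role_accuracy(trials, design),
        asymmetry_summary=asym_summary, anova_asymmetry=anova_asym)

    if reading_records is not None:
        result.speeds = reading_mod.compute_speed(reading_records,
                                                  mode=speed_mode)
        result.correlations = _correlations(spans, result.speeds)
        log.info("correlations: %s", result.correlations.to_dict("records"))
    return result


def render_report(result: AnalysisResult) -> str:
    """Human-readable text report mirroring the standard result tables."""
    lines = ["Visual span analysis", "=" * 60, ""]
    means = (result.spans.groupby(["age_group", "complexity"])
             .agg(span=("span_chars", "mean"), se=("span_chars", "sem"),
                  bits=("span_bits", "mean")).reset_index())
    lines.append("Mean span size (characters; SE) and bits by cell:")
    for _, r in means.iterrows():
        lines.append(f"  {r.age_group:>6} / {r.complexity:<6} "
                     f"span {r.span:5.1f} ({r.se:.1f})   bits {r.bits:5.1f}")
    for label, res in (("characters", result.anova_chars),
                       ("bits", result.anova_bits)):
        lines += ["", f"Mixed ANOVA on span in {label}"
                      f"{' (GG-corrected)' if res.gg_corrected else ''}:"]
        for e in res.effects.values():
            lines.append(f"  {e.effect:<24} F({e.df[0]:.2f}, {e.df[1]:.2f}) ="
                         f" {e.F:7.2f}   p = {e.p:.4g}   eta_p^2 = "
                         f"{e.partial_eta_sq:.2f}")
    lines += ["", "Pairwise age contrasts (Bonferroni-corrected):"]
    for r in result.pairwise_chars:
        lines.append(f"  {r.contrast:<24} t({r.df}) = {r.t:6.2f}   "
                     f"p_bonf = {r.p_bonferroni:.4g}   d = {r.cohens_d:.2f}")
    lines += ["", "Rightward asymmetry (right - left extent, characters):"]
    for _, r in result.asymmetry_summary.iterrows():
        lines.append(f"  {r.age_group:>6} / {r.complexity:<6} "
                     f"{r['mean']:+.2f} (SE {r['sem']:.2f}, n={int(r['count'])})")
    if result.correlations is not None:
        lines += ["", "Span vs reading speed (Pearson):"]
        for _, r in result.correlations.iterrows():
            lines.append(f"  {r.complexity:<6} r = {r.r:5.2f}   "
                         f"p = {r.p:.4g}   n = {int(r.n)}")
    return "\n".join(lines) + "\n"
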