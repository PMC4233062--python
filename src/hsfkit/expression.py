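"""Comparative-Ct qPCR quantification and heat-shock response patterns.

Relative expression uses the comparative ΔCT method against an internal
reference gene: expression = 2^-(Ct_target - Ct_reference) with replicate
Cts averaged arithmetically; fold-change against the untreated control is
2^-ΔΔCT.  Genes are then sorted into four heat-shock response patterns from
their fold-changes at 1 h of heat and 2 h / 4 h of recovery: immediate
up-regulation, late (recovery-phase) up-regulation, inhibition, or no
change.  A genotype comparison flags genes whose wild-type/mutant expression
ratio crosses a declared threshold at any developmental stage.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .io import CtTable

UP_THRESHOLD = 2.0
DOWN_THRESHOLD = 0.5


@dataclass
class RelativeExpression:
    value: float          # 2^-dCt
    sd: float             # propagated from replicate SDs in quadrature

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise ValueError("relative expression must be positive")


@dataclass
class ExpressionProfile:
    gene: str
    reference: str
    expression: dict[str, RelativeExpression] = field(default_factory=dict)

    def fold_change(self, control: str, treated: str) -> float:
        return self.expression[treated].value / self.expression[control].value


@dataclass
class ResponsePattern:
    label: str                        # unchanged | inhibited | immediate_up | late_up
    folds: tuple[float, float, float]  # at 1 h, 2 h, 4 h


def delta_ct(ct_target: list[float], ct_reference: list[float]) -> RelativeExpression:
    """Relative expression 2^-(mean Ct_target - mean Ct_reference)."""
    if not ct_target or not ct_reference:
        raise ValueError("need at least one Ct replicate for target and reference")
    t = np.asarray(ct_target, dtype=float)
    r = np.asarray(ct_reference, dtype=float)
    dct = t.mean() - r.mean()
    sd_dct = math.sqrt(t.std(ddof=1) ** 2 / len(t) + r.std(ddof=1) ** 2 / len(r)) \
        if len(t) > 1 and len(r) > 1 else 0.0
    value = 2.0 ** (-dct)
    sd = value * math.log(2) * sd_dct  # delta-method on 2^-x
    return RelativeExpression(value, sd)


def profile_from_table(table: CtTable, gene: str, reference_gene: str,
                       ) -> ExpressionProfile:
    profile = ExpressionProfile(gene, reference_gene)
    for sample in table.samples:
        target = table.cell(gene, sample)
        ref = table.cell(reference_gene, sample)
        if not target or not ref:
            continue
        profile.expression[sample] = delta_ct(target, ref)
    return profile


def fold_change(profile: ExpressionProfile, control_sample: str,
                treated_sample: str) -> float:
    """2^-ΔΔCT: relative expression of the treated sample over the control."""
    return profile.fold_change(control_sample, treated_sample)


def classify_response(folds: tuple[float, float, float],
                      up_threshold: float = UP_THRESHOLD,
                      down_threshold: float = DOWN_THRESHOLD) -> ResponsePattern:
    """Assign a heat-shock response pattern from folds at 1 h / 2 h / 4 h.

    immediate_up: already up at 1 h of heat.  late_up: not up at 1 h but
    rising monotonically through recovery to above the up threshold.
    inhibited: down at 1 h with no recovery above the up threshold.
    unchanged: everything else.
    """
    f1, f2, f4 = folds
    if f1 >= up_threshold:
        label = "immediate_up"
    elif f1 < up_threshold and f1 < f2 < f4 and f4 >= up_threshold:
        label = "late_up"
    elif f1 <= down_threshold:
        label = "inhibited"
    else:
        label = "unchanged"
    return ResponsePattern(label, (f1, f2, f4))


def classify_from_table(table: CtTable, reference_gene: str,
                        control: str = "CK",
                        timepoints: tuple[str, str, str] = ("1h", "2h", "4h"),
                        up_threshold: float = UP_THRESHOLD,
                        down_threshold: float = DOWN_THRESHOLD,
                        ) -> dict[str, ResponsePattern]:
    """Response pattern for every target gene in a Ct table."""
    out = {}
    for gene in table.genes:
        if gene == reference_gene:
            continue
        profile = profile_from_table(table, gene, reference_gene)
        folds = tuple(profile.fold_change(control, tp) for tp in timepoints)
        out[gene] = classify_response(folds, up_threshold, down_threshold)
    return out


@dataclass
class DifferentialCall:
    gene: str
    stage: str
    ratio: float  # WT / mutant relative expression


def compare_genotypes(profiles_wt: dict[str, ExpressionProfile],
                      profiles_mut: dict[str, ExpressionProfile],
                      min_ratio: float = 2.0) -> list[DifferentialCall]:
    """Per-gene, per-stage WT/mutant expression ratios crossing the threshold.

    A gene is flagged at a stage when the ratio is >= ``min_ratio`` or
    <= 1/``min_ratio``; each flagged (gene, stage) is one call.
    """
    calls = []
    for gene in sorted(profiles_wt):
        if gene not in profiles_mut:
            continue
        wt, mut = profiles_wt[gene], profiles_mut[gene]
        for stage in wt.expression:
            if stage not in mut.expression:
                continue
            ratio = wt.expression[stage].value / mut.expression[stage].value
            if ratio >= min_ratio or ratio <= 1.0 / min_ratio:
                calls.append(DifferentialCall(gene, stage, ratio))
    return calls
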