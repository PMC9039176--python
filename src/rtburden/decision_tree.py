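"""Primary-treatment decision tree: stratify the cohort by radiotherapy exposure.

The tree is collapsed to the minimal structure that determines cardiac
exposure: tumour stage -> radiotherapy yes/no -> laterality.  Left-sided
irradiated tumours receive the high mean heart dose, right-sided the moderate
dose, and women without radiotherapy none.  Defaults are calibrated so the
endpoint proportions reproduce the published cohort stratification exactly;
the internal stage split and per-stage radiotherapy rates are plausible
placeholders (the published endpoint proportions pin down only their
marginal) and are user-configurable for the stage scenarios.
"""

from __future__ import annotations

from dataclasses import dataclass

from .parameters import ValidationError

#: Published endpoint proportions of the stratification.
P_HIGH = 0.3680
P_MOD = 0.3383
P_NONE = 0.2937

_P_RT = P_HIGH + P_MOD  # overall radiotherapy probability, 0.7063
_P_LEFT = P_HIGH / _P_RT  # calibrated laterality split

#: Default share of in-situ (stage 0) disease among stage 0-3 diagnoses and
#: its radiotherapy rate; the stage 1-3 rate is solved so the overall
#: radiotherapy probability matches the published endpoints.
DEFAULT_STAGE0_SHARE = 0.13
DEFAULT_RT_STAGE0 = 0.55


def _default_rt_stage123() -> float:
    return (_P_RT - DEFAULT_STAGE0_SHARE * DEFAULT_RT_STAGE0) / (
        1.0 - DEFAULT_STAGE0_SHARE
    )


def _check_probability(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ValidationError(f"{name}={value} is not a probability")


@dataclass(frozen=True)
class StratumWeights:
    """Proportions of the cohort in each initial exposure state, with doses."""

    p_high: float
    p_mod: float
    p_none: float
    mhd_high: float = 3.6
    mhd_mod: float = 1.9
    mhd_none: float = 0.0

    def __post_init__(self) -> None:
        for name in ("p_high", "p_mod", "p_none"):
            _check_probability(name, getattr(self, name))
        if abs(self.p_high + self.p_mod + self.p_none - 1.0) > 1e-9:
            raise ValidationError("stratum proportions must sum to 1")
        for name in ("mhd_high", "mhd_mod", "mhd_none"):
            if getattr(self, name) < 0.0:
                raise ValidationError(f"{name} must be non-negative")
        if self.mhd_none != 0.0:
            raise ValidationError("the unexposed stratum must have zero dose")

    def items(self) -> list[tuple[str, float, float]]:
        """(stratum, proportion, mean heart dose) triples."""
        return [
            ("high", self.p_high, self.mhd_high),
            ("moderate", self.p_mod, self.mhd_mod),
            ("none", self.p_none, self.mhd_none),
        ]


@dataclass(frozen=True)
class TreeConfig:
    """Branch probabilities of the collapsed treatment tree."""

    p_stage0: float = DEFAULT_STAGE0_SHARE
    rt_stage0: float = DEFAULT_RT_STAGE0
    rt_stage123: float = _default_rt_stage123()
    p_left: float = _P_LEFT

    def __post_init__(self) -> None:
        for name in ("p_stage0", "rt_stage0", "rt_stage123", "p_left"):
            _check_probability(name, getattr(self, name))


def stratify(
    tree: TreeConfig,
    mhd_high: float = 3.6,
    mhd_mod: float = 1.9,
) -> StratumWeights:
    """Marginalize the tree into the three exposure strata.

    high = P(RT) x P(left), moderate = P(RT) x P(right), none = 1 - P(RT),
    with P(RT) marginalized over the stage mix.
    """
    p_rt = tree.p_stage0 * tree.rt_stage0 + (1.0 - tree.p_stage0) * tree.rt_stage123
    return StratumWeights(
        p_high=p_rt * tree.p_left,
        p_mod=p_rt * (1.0 - tree.p_left),
        p_none=1.0 - p_rt,
        mhd_high=mhd_high,
        mhd_mod=mhd_mod,
    )


def rt_only_weights(w: StratumWeights) -> StratumWeights:
    """Restrict to women who actually received radiotherapy (renormalized)."""
    p_rt = w.p_high + w.p_mod
    if p_rt <= 0.0:
        raise ValidationError("no mass in the irradiated strata")
    return StratumWeights(
        p_high=w.p_high / p_rt,
        p_mod=w.p_mod / p_rt,
        p_none=0.0,
        mhd_high=w.mhd_high,
        mhd_mod=w.mhd_mod,
    )


STAGE_SELECTORS = ("all", "stage0_only", "stages123_only")


def stage_scenario_weights(
    tree: TreeConfig,
    stage_selector: str,
    mhd_high: float = 3.6,
    mhd_mod: float = 1.9,
) -> StratumWeights:
    """Override the stage mix (scenario analyses) and restratify."""
    if stage_selector not in STAGE_SELECTORS:
        raise ValidationError(f"unknown stage selector {stage_selector!r}")
    if stage_selector == "stage0_only":
        tree = TreeConfig(1.0, tree.rt_stage0, tree.rt_stage123, tree.p_left)
    elif stage_selector == "stages123_only":
        tree = TreeConfig(0.0, tree.rt_stage0, tree.rt_stage123, tree.p_left)
    return stratify(tree, mhd_high=mhd_high, mhd_mod=mhd_mod)
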