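"""Synthetic crossed participants-x-stimuli data with known ground truth.

The generator implements the same Gaussian model the mixed-model module
fits: each response is

    intercept + sum_t beta_t x_t + b_participant' u + b_stimulus' v + e,

with deviation (-0.5/+0.5) coded factor columns x_t, normal random
effects with the requested per-term SDs, and normal residual noise.
Because the generative effect sizes have closed forms for balanced
designs (:func:`expected_effect_sizes`), every estimator in the package
can be checked by parameter recovery without external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_data import LongTable

__all__ = ["SimSpec", "simulate_crossed", "expected_effect_sizes"]

_SCOPES = ("within_participant", "between_participant", "within_both")


@dataclass(frozen=True)
class SimSpec:
    """Generative parameters for a crossed two-level design.

    ``factors`` maps each factor name to its scope: a
    ``between_participant`` factor splits the participants into two
    groups (and, if stimuli are present, varies within stimuli); a
    ``within_participant`` factor is seen by every participant (and, if
    stimuli are present, splits the stimuli between its levels, as when
    different texts instantiate different conditions); a
    ``within_both`` factor crosses both random units — every participant
    responds to every stimulus under both levels, as when the same items
    are presented in two conditions.

    ``fixed`` gives true coefficients per term on the deviation (+-0.5)
    scale, so a main-effect coefficient is the level difference.
    Component SDs are per random term, with ``"1"`` the intercept;
    slopes are only allowed for factors that vary within the unit.
    ``replicates`` repeats each design cell. ``missing_rate`` drops rows
    independently (missing completely at random).  ``seed`` is
    mandatory: the same seed yields a bit-identical table.
    """

    n_participants: int
    seed: int
    n_stimuli: int = 0
    factors: dict[str, str] = field(default_factory=dict)
    intercept: float = 0.0
    fixed: dict[str, float] = field(default_factory=dict)
    participant_components: dict[str, float] = field(default_factory=lambda: {"1": 1.0})
    stimulus_components: dict[str, float] = field(default_factory=dict)
    residual_sd: float = 1.0
    replicates: int = 1
    missing_rate: float = 0.0

    def __post_init__(self):
        for f, scope in self.factors.items():
            if scope not in _SCOPES:
                raise ValueError(f"factor {f!r}: unknown scope {scope!r}")
        for comp, owner in ((self.participant_components, "participant"),
                            (self.stimulus_components, "stimulus")):
            for term, sd in comp.items():
                if sd < 0:
                    raise ValueError(f"{owner} SD for {term!r} is negative")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must be in [0, 1)")
        if self.residual_sd < 0:
            raise ValueError("residual_sd must be >= 0")
        if self.n_stimuli and not self.factors:
            return
        self._validate_slopes()

    def _validate_slopes(self) -> None:
        for term in self.participant_components:
            if term == "1":
                continue
            for f in term.split(":"):
                if self.factors.get(f) not in ("within_participant", "within_both"):
                    raise ValueError(
                        f"participant slope on {term!r} is impossible: "
                        f"{f!r} does not vary within participants"
                    )
        for term in self.stimulus_components:
            if term == "1":
                continue
            if self.n_stimuli == 0:
                raise ValueError("stimulus components given but n_stimuli=0")
            for f in term.split(":"):
                if self.factors.get(f) not in ("between_participant", "within_both"):
                    raise ValueError(
                        f"stimulus slope on {term!r} is impossible: "
                        f"{f!r} does not vary within stimuli"
                    )

    @property
    def within_factors(self) -> list[str]:
        """Factors that split the stimuli (within participant, between
        stimuli)."""
        return [f for f, s in self.factors.items() if s == "within_participant"]

    @property
    def between_factors(self) -> list[str]:
        return [f for f, s in self.factors.items() if s == "between_participant"]

    @property
    def crossed_factors(self) -> list[str]:
        return [f for f, s in self.factors.items() if s == "within_both"]


def _codes(level_label: str) -> float:
    # levels are "<factor>0"/"<factor>1": deviation codes -0.5/+0.5
    return -0.5 if level_label.endswith("0") else 0.5


def _assign_levels(units: list[str], factors: list[str], what: str) -> pd.DataFrame:
    """Split units equally over the 2^k cells of ``factors``."""
    n_cells = 2 ** len(factors)
    if len(units) % n_cells:
        raise ValueError(
            f"{what}: {len(units)} units cannot be split equally over "
            f"{n_cells} cells of {factors}"
        )
    rows = []
    for i, u in enumerate(units):
        cell = i % n_cells
        rec = {"unit": u}
        for j, f in enumerate(factors):
            rec[f] = f"{f}{(cell >> j) & 1}"
        rows.append(rec)
    return pd.DataFrame(rows)


def _term_column(term: str, frame: pd.DataFrame) -> np.ndarray:
    col = np.ones(len(frame))
    for f in term.split(":"):
        col = col * frame[f].map(_codes).to_numpy()
    return col


def _draw_effects(rng: np.random.Generator, units: list[str],
                  components: dict[str, float]) -> pd.DataFrame:
    terms = list(components)
    draws = rng.normal(size=(len(units), len(terms))) * np.array(
        [components[t] for t in terms])
    return pd.DataFrame(draws, index=units, columns=terms)


def simulate_crossed(spec: SimSpec) -> LongTable:
    """Generate one dataset from ``spec`` (deterministic given the seed)."""
    rng = np.random.default_rng(spec.seed)
    participants = [f"p{i + 1:04d}" for i in range(spec.n_participants)]
    p_assign = _assign_levels(participants, spec.between_factors,
                              "participants").set_index("unit")

    if spec.n_stimuli > 0:
        stimuli = [f"s{i + 1:04d}" for i in range(spec.n_stimuli)]
        s_assign = _assign_levels(stimuli, spec.within_factors,
                                  "stimuli").set_index("unit")
        crossed_levels = [[f"{f}0", f"{f}1"] for f in spec.crossed_factors]
        base = pd.MultiIndex.from_product(
            [participants, stimuli, *crossed_levels, range(spec.replicates)],
            names=["participant", "stimulus", *spec.crossed_factors, "rep"],
        ).to_frame(index=False)
        for f in spec.between_factors:
            base[f] = base["participant"].map(p_assign[f])
        for f in spec.within_factors:
            base[f] = base["stimulus"].map(s_assign[f])
    else:
        within = [*spec.within_factors, *spec.crossed_factors]
        cells = pd.MultiIndex.from_product(
            [[f"{f}0", f"{f}1"] for f in within] or [[None]],
            names=within or ["_none"]).to_frame(index=False)
        if "_none" in cells.columns:
            cells = cells.drop(columns="_none")
        frames = []
        for rep in range(spec.replicates):
            for p in participants:
                c = cells.copy()
                c["participant"] = p
                c["rep"] = rep
                frames.append(c)
        base = pd.concat(frames, ignore_index=True)
        for f in spec.between_factors:
            base[f] = base["participant"].map(p_assign[f])
        # a participant slope needs >1 cell per participant
        if within == [] and any(
                t != "1" for t in spec.participant_components):
            raise ValueError("impossible design: participant slopes "
                             "without within-participant factors")

    y = np.full(len(base), spec.intercept, dtype=float)
    for term, beta in spec.fixed.items():
        y += beta * _term_column(term, base)

    p_eff = _draw_effects(rng, participants, spec.participant_components)
    for term in spec.participant_components:
        col = (np.ones(len(base)) if term == "1"
               else _term_column(term, base))
        y += base["participant"].map(p_eff[term]).to_numpy() * col
    if spec.n_stimuli > 0 and spec.stimulus_components:
        s_eff = _draw_effects(rng, stimuli, spec.stimulus_components)
        for term in spec.stimulus_components:
            col = (np.ones(len(base)) if term == "1"
                   else _term_column(term, base))
            y += base["stimulus"].map(s_eff[term]).to_numpy() * col
    y += rng.normal(scale=spec.residual_sd, size=len(base))

    base = base.copy()
    base["response"] = y
    base["rep"] = base["rep"].astype(str)
    if spec.missing_rate > 0:
        keep = rng.random(len(base)) >= spec.missing_rate
        base = base.loc[keep].reset_index(drop=True)
    return LongTable(
        base,
        response="response",
        participant="participant",
        stimulus="stimulus" if spec.n_stimuli > 0 else None,
        factors=list(spec.factors),
        replicates=["rep"],
    )


def _term_variance(term: str, beta: float) -> float:
    # +-0.5 coding per factor: a k-factor product column has variance 4^-k
    k = len(term.split(":"))
    return beta**2 * 0.25**k


def _component_variances(spec: SimSpec, components: dict[str, float]) -> float:
    total = 0.0
    for term, sd in components.items():
        if term == "1":
            total += sd**2
        else:
            k = len(term.split(":"))
            total += sd**2 * 0.25**k
    return total


def expected_effect_sizes(spec: SimSpec,
                          center_by: str = "participant") -> dict[str, dict]:
    """Closed-form eta squared and eta squared within per fixed term.

    For the balanced generative model, eta^2 of a term is its fixed
    variance over the total variance (all fixed terms + all random
    components + residual).  Eta squared within under ``center_by``
    drops the centered unit's intercept variance and any fixed term
    that is constant within the centered units (those terms have no
    within value: None).  Undefined for unbalanced specs
    (missing_rate > 0), where the closed form does not hold.
    """
    if spec.missing_rate > 0:
        raise ValueError("closed-form effect sizes require a balanced "
                         "spec (missing_rate == 0)")
    if center_by not in ("participant", "stimulus"):
        raise ValueError("center_by must be 'participant' or 'stimulus'")
    if center_by == "stimulus" and spec.n_stimuli == 0:
        raise ValueError("no stimulus unit in this spec")

    var_terms = {t: _term_variance(t, b) for t, b in spec.fixed.items()}
    var_random = (_component_variances(spec, spec.participant_components)
                  + (_component_variances(spec, spec.stimulus_components)
                     if spec.n_stimuli else 0.0))
    total = sum(var_terms.values()) + var_random + spec.residual_sd**2

    if center_by == "participant":
        unit_comp = spec.participant_components
        between = set()
        for t in spec.fixed:
            if all(spec.factors[f] == "between_participant"
                   for f in t.split(":")):
                between.add(t)
    else:
        unit_comp = spec.stimulus_components
        between = set()
        for t in spec.fixed:
            if all(spec.factors[f] == "within_participant"
                   for f in t.split(":")):
                between.add(t)
    total_within = total - unit_comp.get("1", 0.0)**2 - sum(
        var_terms[t] for t in between)

    out: dict[str, dict] = {}
    for term, v in var_terms.items():
        out[term] = {
            "eta2": v / total,
            "eta2_w": None if term in between else v / total_within,
        }
    return out
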