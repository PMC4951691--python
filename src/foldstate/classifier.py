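"""Evidence-integrating conformational-state classifier.

Combines sequence (charge-hydropathy side), hydrodynamic (Q-factor band,
Rh-deviation from per-state scaling laws), SAXS (Kratky shape), and
titration (unfolding cooperativity, ANS affinity, tryptophan lambda-max)
evidence into a single conformational verdict with per-state scores and a
human-readable rationale.

The vote is linear and additive: each evidence channel carries a weight
(default: all equal) split evenly among the states it supports; scores are
normalized to sum to one.  This mirrors how such verdicts are reached in
practice — qualitative rule accumulation — while keeping every step
traceable and the weights overridable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from .config import default_config
from .hydrodynamics import conformer_rh, q_classify

STATES = ("native_globular", "molten_globule", "pre_molten_globule", "extended_coil")

# which classifier state each Q-band / scaling-law label supports
_Q_BAND_STATES = {
    "sphere": ("native_globular",),
    "globular": ("native_globular",),
    "molten_globule": ("molten_globule",),
    "pre_molten_globule": ("pre_molten_globule",),
    "random_coil": ("extended_coil",),
}
_SCALING_STATES = {
    "native": "native_globular",
    "molten_globule": "molten_globule",
    "pre_molten_globule": "pre_molten_globule",
    "urea_unfolded": "extended_coil",
    "gdmcl_unfolded": "extended_coil",
}


@dataclass
class EvidenceBundle:
    """Optional per-channel evidence; at least two channels for a full verdict."""
    ch_class: str | None = None                      # 'native_side' | 'unfolded_side'
    q_value: float | None = None
    q_classes: list[str] | None = None               # bands containing Q
    rh_state_deviations: dict[str, float] | None = None
    kratky_class: str | None = None
    unfolding_verdicts: list[str] | None = None
    ans_affinity_flag: bool | None = None
    trp_lambda_max: float | None = None              # nm

    @classmethod
    def from_json(cls, path: str | Path) -> "EvidenceBundle":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass
class ConformationalAssessment:
    primary_state: str
    compatible_states: list[tuple[str, float]]       # ranked (state, score)
    rationale: list[str]
    confidence: str                                  # 'strong' | 'moderate' | 'weak'

    def as_dict(self) -> dict:
        return {
            "primary_state": self.primary_state,
            "compatible_states": [
                {"state": s, "score": v} for s, v in self.compatible_states
            ],
            "rationale": self.rationale,
            "confidence": self.confidence,
        }


def rh_state_deviations(
    mass_da: float, rh_obs_nm: float, config: dict | None = None
) -> dict[str, float]:
    """Relative deviation of an observed Rh from each state's scaling law.

    For each state: |Rh_obs - Rh_pred(mass, state)| / Rh_pred(mass, state).
    The state with the smallest deviation is the hydrodynamically most
    consistent conformer at that mass.
    """
    if mass_da <= 0 or rh_obs_nm <= 0:
        raise ValueError("mass and Rh must be positive")
    cfg = config or default_config()
    out = {}
    for state in cfg["scaling_laws"]:
        pred = conformer_rh(mass_da, state, cfg)
        out[state] = abs(rh_obs_nm - pred) / pred
    return out


def _vote(scores, rationale, states, weight, reason):
    if not states:
        return
    share = weight / len(states)
    for s in states:
        scores[s] += share
    rationale.append(reason)


def classify_state(
    bundle: EvidenceBundle, config: dict | None = None
) -> ConformationalAssessment:
    """Integrate an evidence bundle into a conformational assessment.

    Channel votes: charge-hydropathy native side supports {native, MG};
    Q-band membership supports its band states; the minimal Rh deviation
    supports its state; Kratky globular_compact supports native,
    compact_plus_flexible supports MG, extended supports {pre-MG, coil};
    non-cooperative unfolding supports {MG, pre-MG, coil}, cooperative
    supports native; high ANS affinity supports MG; a lambda-max in the
    partially-buried window supports MG.  Ties break by channel priority
    (Kratky first).  Deterministic: identical bundles yield identical output.
    """
    cfg = config or default_config()
    ccfg = cfg["classifier"]
    weights = ccfg["weights"]
    scores = {s: 0.0 for s in STATES}
    rationale: list[str] = []
    top_vote_channel: dict[str, str] = {}   # state -> highest-priority channel voting for it
    n_channels = 0

    def record(channel, states, reason):
        nonlocal n_channels
        if not states:
            return
        n_channels += 1
        _vote(scores, rationale, states, weights[channel], reason)
        for s in states:
            top_vote_channel.setdefault(s + ":" + channel, channel)

    if bundle.ch_class is not None:
        if bundle.ch_class == "native_side":
            record("charge_hydropathy",
                   ("native_globular", "molten_globule"),
                   "charge-hydropathy plot places the sequence on the native "
                   "side: compatible with a folded or molten-globule protein")
        else:
            record("charge_hydropathy", ("extended_coil", "pre_molten_globule"),
                   "charge-hydropathy plot places the sequence on the "
                   "natively-unfolded side")

    if bundle.q_value is not None or bundle.q_classes is not None:
        bands = bundle.q_classes
        if bands is None:
            bands, _ = q_classify(bundle.q_value, cfg)
        supported = sorted({s for b in bands for s in _Q_BAND_STATES.get(b, ())})
        qtxt = f"{bundle.q_value:.3g}" if bundle.q_value is not None else "?"
        record("q_band", tuple(supported),
               f"Q-factor {qtxt} falls in band(s) {', '.join(bands)}")

    if bundle.rh_state_deviations:
        best = min(bundle.rh_state_deviations, key=bundle.rh_state_deviations.get)
        record("rh_deviation", (_SCALING_STATES.get(best, best),),
               f"observed Rh deviates least ({bundle.rh_state_deviations[best]:.1%}) "
               f"from the {best} scaling law")

    if bundle.kratky_class is not None:
        mapping = {
            "globular_compact": ("native_globular",),
            "compact_plus_flexible": ("molten_globule",),
            "extended": ("pre_molten_globule", "extended_coil"),
        }
        record("kratky", mapping[bundle.kratky_class],
               f"Kratky profile shape is {bundle.kratky_class}")

    if bundle.unfolding_verdicts:
        for verdict in bundle.unfolding_verdicts:
            if verdict == "cooperative":
                record("unfolding", ("native_globular",),
                       "cooperative (sigmoidal) unfolding transition")
            else:
                record("unfolding",
                       ("molten_globule", "pre_molten_globule", "extended_coil"),
                       "low-cooperativity (near-linear) unfolding transition")

    if bundle.ans_affinity_flag:
        record("ans", ("molten_globule",),
               "high ANS affinity: solvent-accessible hydrophobic surface")

    if bundle.trp_lambda_max is not None:
        lo, hi = ccfg["lambda_max_buried_range"]
        if lo < bundle.trp_lambda_max < hi:
            record("lambda_max", ("molten_globule",),
                   f"tryptophan lambda-max {bundle.trp_lambda_max:g} nm: partially "
                   "buried fluorophores (neither fully exposed nor fully buried)")

    partial = n_channels < 2
    if partial:
        rationale.append("fewer than two evidence channels: partial assessment")

    total = sum(scores.values())
    if total == 0:
        raise ValueError("bundle carries no usable evidence")
    norm = {s: v / total for s, v in scores.items()}

    priority = ccfg["priority"]

    def sort_key(item):
        state, score = item
        # ties break by the priority rank of the best channel voting for the state
        ranks = [priority.index(ch) for key, ch in top_vote_channel.items()
                 if key.startswith(state + ":")]
        return (-score, min(ranks) if ranks else len(priority))

    ranked = sorted(norm.items(), key=sort_key)
    ranked = [(s, v) for s, v in ranked if v > 0]
    primary, top = ranked[0]
    margin = top - ranked[1][1] if len(ranked) > 1 else top

    conf_cfg = ccfg["confidence"]
    if partial or margin < conf_cfg["weak_margin"]:
        confidence = "weak"
    elif top >= conf_cfg["strong_top"] and margin >= conf_cfg["strong_margin"]:
        confidence = "strong"
    else:
        confidence = "moderate"
    if confidence == "weak" and len(ranked) > 1 and margin < conf_cfg["weak_margin"]:
        rationale.append(
            f"top two states ({ranked[0][0]}, {ranked[1][0]}) are within "
            f"{margin:.3f} of each other: evidence is conflicting or thin"
        )
    return ConformationalAssessment(primary, ranked, rationale, confidence)
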