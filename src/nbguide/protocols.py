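"""Scripted end-to-end experiment recipes at desk scale.

Two study shapes are provided: multi-round bench-style campaigns on the
perfused-tissue phantom configuration (generous 600 s cap, noise profile
improving round over round as a stand-in for model updates), and live-style
campaigns alternating normovolemic and hypovolemic conditions under a
180 s cap.  Campaigns are fully deterministic given their master seed and
are summarised with :func:`nbguide.evaluation.trial_statistics`.

Also provided are fixture records rebuilt from published bench-test count
tables, used to regression-test the trial statistics against printed
percentages.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import evaluation, guidance, phantom
from .types import TrialRecord

#: Desk-scale trial frame geometry: 0.25 mm/px at the 6 cm survey depth.
TRIAL_SCENE = phantom.SceneParams(image_height_px=240, image_width_px=160)

EX_VIVO_TIME_CAP_S = 600.0
IN_VIVO_TIME_CAP_S = 180.0
HYPOVOLEMIC_VOLEMIA = 0.65


@dataclass(frozen=True)
class CampaignConfig:
    """One scripted campaign: subjects x trials with per-trial conditions."""

    n_subjects: int = 8
    trials_per_subject: int = 8
    condition_schedule: Optional[Sequence[str]] = None  # per trial index
    noise_profile: str | phantom.OracleNoise = "low"
    time_cap_s: float = IN_VIVO_TIME_CAP_S
    operator: guidance.OperatorModel = field(
        default_factory=guidance.OperatorModel)
    scene: phantom.SceneParams = TRIAL_SCENE
    round_label: str = ""
    master_seed: int = 0

    def __post_init__(self):
        if self.time_cap_s <= 0:
            raise ValueError("time cap must be positive")
        if self.n_subjects < 1 or self.trials_per_subject < 1:
            raise ValueError("subjects and trials must be >= 1")
        if self.condition_schedule is not None and \
                len(self.condition_schedule) != self.trials_per_subject:
            raise ValueError("condition schedule length must equal trial count")

    def resolved_noise(self) -> phantom.OracleNoise:
        if isinstance(self.noise_profile, phantom.OracleNoise):
            return self.noise_profile
        return phantom.NOISE_PROFILES[self.noise_profile]


def _scene_for(config: CampaignConfig, condition: str) -> phantom.SceneParams:
    if condition == "hypovolemic":
        return dataclasses.replace(config.scene, volemia=HYPOVOLEMIC_VOLEMIA)
    return config.scene


def run_campaign(config: CampaignConfig) -> tuple[list[TrialRecord], dict]:
    """Run every trial of a campaign; returns records and their summary."""
    rng = np.random.default_rng(config.master_seed)
    noise = config.resolved_noise()
    schedule = config.condition_schedule or \
        ["normovolemic"] * config.trials_per_subject
    records: list[TrialRecord] = []
    for subj in range(config.n_subjects):
        for t, condition in enumerate(schedule):
            record = guidance.run_trial(
                phantom_config=_scene_for(config, condition),
                operator=config.operator,
                noise=noise,
                time_cap_s=config.time_cap_s,
                seed=int(rng.integers(2**31)),
                round_label=config.round_label,
                subject=f"subject-{subj + 1:02d}")
            records.append(record)
    return records, evaluation.trial_statistics(records)


def ex_vivo_style_campaign(master_seed: int = 0,
                           n_rounds: int = 2,
                           trials_per_round: int = 12) -> CampaignConfig | list:
    """Bench-style multi-round campaign configs (noise eases per round)."""
    profiles = ["moderate", "low", "low", "zero"]
    configs = []
    for r in range(n_rounds):
        n_subjects = max(1, trials_per_round // 6)
        configs.append(CampaignConfig(
            n_subjects=n_subjects,
            trials_per_subject=trials_per_round // n_subjects,
            noise_profile=profiles[min(r, len(profiles) - 1)],
            time_cap_s=EX_VIVO_TIME_CAP_S,
            round_label=f"round-{r + 1}",
            master_seed=master_seed + r))
    return configs


def in_vivo_style_campaign(master_seed: int = 0, n_subjects: int = 8,
                           trials_per_subject: int = 8) -> CampaignConfig:
    """Live-style campaign alternating normo/hypovolemic conditions."""
    schedule = ["normovolemic" if i % 2 == 0 else "hypovolemic"
                for i in range(trials_per_subject)]
    return CampaignConfig(
        n_subjects=n_subjects, trials_per_subject=trials_per_subject,
        condition_schedule=schedule, noise_profile="low",
        time_cap_s=IN_VIVO_TIME_CAP_S, round_label="in-vivo-style",
        master_seed=master_seed)


#: Published bench-test counts: round -> (attempts, successes).
TABLE3_COUNTS = {
    "round-1": (9, 2),
    "round-2": (38, 28),
    "round-3": (67, 65),
    "round-4": (46, 43),
}

#: Published live-test counts: (attempts, successes), by condition.
IN_VIVO_COUNTS = {"attempts": 60, "successes": 59,
                  "normovolemic_n": 35, "hypovolemic_n": 25}


def fixture_table3() -> list[TrialRecord]:
    """Bench-test records carrying only success flags and round labels.

    Per-attempt times are not recoverable from the published counts, so
    ``elapsed_s`` is left unset; the records support success-rate
    regression only.
    """
    records = []
    for label, (attempts, successes) in TABLE3_COUNTS.items():
        for i in range(attempts):
            records.append(TrialRecord(
                success=i < successes, elapsed_s=None, round_label=label))
    return records


def fixture_in_vivo() -> list[TrialRecord]:
    """Live-test records rebuilt from the published success counts."""
    c = IN_VIVO_COUNTS
    records = []
    for i in range(c["attempts"]):
        condition = ("normovolemic" if i < c["normovolemic_n"]
                     else "hypovolemic")
        records.append(TrialRecord(
            success=i < c["successes"], elapsed_s=None,
            condition=condition, round_label="in-vivo"))
    return records
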