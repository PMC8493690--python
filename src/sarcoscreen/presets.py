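"""Scenario presets mirroring the three screening experiment designs.

* ``dose_response`` — vehicle control plus three sunitinib doses with
  strongly dose-dependent sarcomere disruption.
* ``washout_recovery`` — the same dose groups imaged at three
  timepoints after drug washout (0 h, 72 h, 144 h), with severity
  relaxing toward control; at 144 h all groups equal the control
  (complete recovery).  Each timepoint is an independent plate, since
  cells are fixed before imaging.
* ``rescue_cotreatment`` — sunitinib alone versus sunitinib plus two
  doses of the MST1/2 inhibitor XMU-MP-1; rescue severity sits strictly
  between sunitinib-alone and control.  Besides the many-to-one
  comparison against the vehicle control, the rescue doses are tested
  against the sunitinib-alone group with an increasing alternative.

Severities are chosen to qualitatively mirror the published ordering
(strong dose-dependent disruption, near-complete recovery after 144 h
of washout, partial rescue), not calibrated to any reported
percentages.  The control healthy fraction is 0.8: even vehicle wells
contain some cells without well-organized sarcomeres.
"""

from __future__ import annotations

from dataclasses import dataclass

from sarcoscreen.core import ConfigurationError
from sarcoscreen.simulate import GroupSpec, SimConfig

PRESET_NAMES = ("dose_response", "washout_recovery", "rescue_cotreatment")

CONTROL_HEALTHY_FRACTION = 0.8


@dataclass
class TrendAnalysisSpec:
    """One step-down trend analysis: doses (ordered) against a control."""

    name: str
    control_label: str
    dose_labels: list
    direction: str = "decreasing"
    alpha: float = 0.025


@dataclass
class ScenarioPreset:
    name: str
    description: str
    groups: list
    analyses: list
    timepoint: str = ""


def _sun_groups(fractions) -> list:
    doses = [0.3, 1.0, 3.0]
    groups = [GroupSpec(label="DMSO", dose_uM=0.0, is_control=True,
                        healthy_fraction=fractions[0])]
    for dose, hf in zip(doses, fractions[1:]):
        groups.append(GroupSpec(label=f"SUN_{dose:g}uM", dose_uM=dose,
                                healthy_fraction=hf))
    return groups


def dose_response_preset() -> ScenarioPreset:
    groups = _sun_groups([CONTROL_HEALTHY_FRACTION, 0.52, 0.11, 0.01])
    return ScenarioPreset(
        name="dose_response",
        description="72 h sunitinib exposure, 3 doses vs vehicle control",
        groups=groups,
        analyses=[TrendAnalysisSpec(
            name="hsi_vs_control", control_label="DMSO",
            dose_labels=[g.label for g in groups[1:]], direction="decreasing",
        )],
    )


# Healthy fractions per washout timepoint (DMSO, 0.3, 1, 3 uM sunitinib).
WASHOUT_SEVERITIES = {
    "0h": [CONTROL_HEALTHY_FRACTION, 0.52, 0.11, 0.01],
    "72h": [CONTROL_HEALTHY_FRACTION, 0.69, 0.55, 0.13],
    "144h": [CONTROL_HEALTHY_FRACTION] * 4,  # complete recovery
}


def washout_preset(timepoint: str) -> ScenarioPreset:
    if timepoint not in WASHOUT_SEVERITIES:
        raise ConfigurationError(
            f"unknown washout timepoint {timepoint!r}; "
            f"expected one of {sorted(WASHOUT_SEVERITIES)}"
        )
    groups = _sun_groups(WASHOUT_SEVERITIES[timepoint])
    return ScenarioPreset(
        name="washout_recovery",
        description=f"sarcomere recovery {timepoint} after sunitinib washout",
        groups=groups,
        analyses=[TrendAnalysisSpec(
            name="hsi_vs_control", control_label="DMSO",
            dose_labels=[g.label for g in groups[1:]], direction="decreasing",
        )],
        timepoint=timepoint,
    )


def rescue_preset() -> ScenarioPreset:
    groups = [
        GroupSpec(label="DMSO", dose_uM=0.0, is_control=True,
                  healthy_fraction=CONTROL_HEALTHY_FRACTION),
        GroupSpec(label="SUN_1uM", dose_uM=1.0, healthy_fraction=0.16),
        GroupSpec(label="SUN_1uM+XMU_0.3uM", dose_uM=0.3, healthy_fraction=0.45),
        GroupSpec(label="SUN_1uM+XMU_1uM", dose_uM=1.0, healthy_fraction=0.60),
    ]
    return ScenarioPreset(
        name="rescue_cotreatment",
        description="1 uM sunitinib with or without XMU-MP-1 co-treatment",
        groups=groups,
        analyses=[
            TrendAnalysisSpec(
                name="hsi_vs_control", control_label="DMSO",
                dose_labels=["SUN_1uM+XMU_1uM", "SUN_1uM+XMU_0.3uM", "SUN_1uM"],
                direction="decreasing",
            ),
            TrendAnalysisSpec(
                name="rescue_vs_sunitinib", control_label="SUN_1uM",
                dose_labels=["SUN_1uM+XMU_0.3uM", "SUN_1uM+XMU_1uM"],
                direction="increasing",
            ),
        ],
    )


def get_preset(name: str, timepoint: str = "0h") -> ScenarioPreset:
    if name == "dose_response":
        return dose_response_preset()
    if name == "washout_recovery":
        return washout_preset(timepoint)
    if name == "rescue_cotreatment":
        return rescue_preset()
    raise ConfigurationError(f"unknown preset {name!r}; expected {PRESET_NAMES}")


def preset_sim_config(preset: ScenarioPreset, seed: int,
                      wells_per_group: int = 5, **overrides) -> SimConfig:
    """Build the sarcomere-mode SimConfig for a scenario preset."""
    return SimConfig(groups=preset.groups, rng_seed=seed,
                     wells_per_group=wells_per_group, **overrides)
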