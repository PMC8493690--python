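"""Shared data containers and error types for the sarcoscreen pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

SARCOMERE_60X = "sarcomere_60x"
YAP_4X = "yap_4x"
MODES = (SARCOMERE_60X, YAP_4X)


class ConfigurationError(ValueError):
    """Raised when a simulation or run configuration is invalid."""


class GenerationError(RuntimeError):
    """Raised when a synthetic field cannot be generated as requested."""


@dataclass
class FieldImage:
    """One microscope field: two 16-bit channels plus acquisition metadata.

    Channel 1 is the Hoechst (nuclei) channel; channel 2 carries the
    marker of interest — alpha-actinin at 60x (sarcomere mode) or active
    YAP1 at 4x (translocation mode).
    """

    well: str
    field: int
    channels: np.ndarray  # (2, rows, cols) uint16
    pixel_size_um: float
    mode: str = SARCOMERE_60X

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels)
        if self.channels.ndim != 3 or self.channels.shape[0] != 2:
            raise ConfigurationError(
                f"channels must be (2, rows, cols), got {self.channels.shape}"
            )
        if self.pixel_size_um <= 0:
            raise ConfigurationError("pixel_size_um must be positive")
        if self.mode not in MODES:
            raise ConfigurationError(f"unknown mode {self.mode!r}")

    @property
    def nuclei(self) -> np.ndarray:
        return self.channels[0]

    @property
    def marker(self) -> np.ndarray:
        return self.channels[1]


@dataclass
class CellRecord:
    """Per-cell measurements produced by segmentation and scoring."""

    well: str
    field: int
    cell_id: int
    centroid_row: float
    centroid_col: float
    nucleus_area_px: int
    z_line_lengths_um: list = field(default_factory=list)
    mean_z_length_um: float = float("nan")  # NaN == undefined (no Z-line)
    yap_nuclear_mean: float = float("nan")
    yap_cytoplasm_mean: float = float("nan")
    yap_measurable: bool = False
    healthy: bool = False
    yap_nuclear: bool = False


@dataclass
class WellMetrics:
    """Per-well aggregates: cell counts, HSI and YAP1 nuclear index."""

    well: str
    group_label: str = ""
    n_cells_total: int = 0
    n_healthy: int = 0
    hsi: float = float("nan")
    n_measurable: int = 0
    n_yap_nuclear: int = 0
    yap_index: float = float("nan")
    low_count: bool = False


@dataclass
class GroupResult:
    """Per-group summary of one per-well metric relative to control."""

    group_label: str
    dose_uM: float
    n_wells: int
    well_values: list
    mean: float
    sd: float
    percent_of_control: float
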