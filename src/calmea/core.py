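"""Shared containers for fluorescence-field recordings.

Conventions used throughout the package: frames are 0-based, image
coordinates are 0-based ``(row, col)`` pixels, and time is in seconds.
The stimulus is applied at the *start* of ``stimulus_frame``; frames
before it are the baseline period.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np


class ConfigurationError(ValueError):
    """Raised when a generator or pipeline configuration is invalid."""


class GenerationError(RuntimeError):
    """Raised when synthetic-data generation cannot satisfy its constraints
    (e.g. cell placement fails after bounded retries)."""


@dataclass
class CellTrace:
    """One cell's fluorescence time series.

    Attributes
    ----------
    cell_id : int
        Unique identifier within a field.
    fluorescence : np.ndarray
        Intensity per frame, arbitrary units, length = number of frames.
    centroid : (float, float), optional
        ``(row, col)`` position in pixels, if the trace came from an image.
    is_responder : bool, optional
        Ground-truth responder flag for synthetic traces.
    """

    cell_id: int
    fluorescence: np.ndarray
    centroid: Optional[tuple] = None
    is_responder: Optional[bool] = None

    def __post_init__(self) -> None:
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.fluorescence.ndim != 1:
            raise ValueError("fluorescence must be a 1-D sequence")


@dataclass
class FieldRecording:
    """A single stimulus experiment on one image field.

    ``traces`` is an ``(n_cells, n_frames)`` array of fluorescence values,
    one row per cell.  ``frame_times`` gives the acquisition time of each
    frame in seconds; ``stimulus_frame`` is the 0-based index of the first
    frame acquired after compound addition.
    """

    traces: np.ndarray
    stimulus_frame: int
    frame_times: Optional[np.ndarray] = None
    cell_ids: Optional[Sequence[int]] = None
    centroids: Optional[np.ndarray] = None
    condition: str = ""

    def __post_init__(self) -> None:
        self.traces = np.atleast_2d(np.asarray(self.traces, dtype=float))
        n_cells, n_frames = self.traces.shape
        if not 0 <= self.stimulus_frame < n_frames:
            raise ConfigurationError(
                f"stimulus_frame {self.stimulus_frame} outside 0..{n_frames - 1}"
            )
        if self.frame_times is None:
            self.frame_times = np.arange(n_frames, dtype=float)
        else:
            self.frame_times = np.asarray(self.frame_times, dtype=float)
            if self.frame_times.shape != (n_frames,):
                raise ConfigurationError("frame_times length must equal frame count")
        if self.cell_ids is None:
            self.cell_ids = list(range(n_cells))
        elif len(self.cell_ids) != n_cells:
            raise ConfigurationError("cell_ids length must equal number of cells")
        if self.centroids is not None:
            self.centroids = np.asarray(self.centroids, dtype=float)
            if self.centroids.shape != (n_cells, 2):
                raise ConfigurationError("centroids must be (n_cells, 2)")

    @property
    def n_cells(self) -> int:
        return self.traces.shape[0]

    @property
    def n_frames(self) -> int:
        return self.traces.shape[1]

    def cell(self, index: int) -> CellTrace:
        """Return a single :class:`CellTrace` by positional index."""
        centroid = None if self.centroids is None else tuple(self.centroids[index])
        return CellTrace(
            cell_id=int(self.cell_ids[index]),
            fluorescence=self.traces[index],
            centroid=centroid,
        )
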