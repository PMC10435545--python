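"""Deconvolved calcium event rasters.

An :class:`EventRaster` holds the deconvolved event train (nonnegative event
amplitudes/counts) of every recorded neuron over a session, sampled at the
imaging frame rate (20 frames/s), together with the pathway tag (dSPN or
iSPN) of the recorded population.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class EventRaster:
    """Neurons x frames deconvolved event amplitudes.

    Attributes
    ----------
    events
        Array ``(n_neurons, n_frames)``, nonnegative.
    rate
        Imaging frame rate in frames/s (20 by default).
    pathway
        Optional population tag, ``"dSPN"`` or ``"iSPN"``.
    """

    events: np.ndarray
    rate: float = 20.0
    pathway: str | None = None
    session_id: str | None = None

    def __post_init__(self) -> None:
        self.events = np.asarray(self.events, dtype=float)
        if self.events.ndim != 2:
            raise ValueError("events must be 2-D (neurons x frames)")
        if not np.isfinite(self.events).all():
            raise ValueError("events must be finite")
        if (self.events < 0).any():
            raise ValueError("events must be nonnegative")
        if self.rate <= 0:
            raise ValueError("rate must be positive")

    @property
    def n_neurons(self) -> int:
        return int(self.events.shape[0])

    @property
    def n_frames(self) -> int:
        return int(self.events.shape[1])

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.rate

    def mean_rates(self) -> np.ndarray:
        """Per-neuron overall event rate in events/s."""
        return self.events.mean(axis=1) * self.rate

    def subset(self, neuron_idx) -> "EventRaster":
        return EventRaster(self.events[np.asarray(neuron_idx)], self.rate,
                           self.pathway, self.session_id)

    # ---- IO -------------------------------------------------------------
    def to_csv(self, path) -> None:
        pd.DataFrame(self.events).to_csv(path, index_label="neuron")

    @classmethod
    def from_csv(cls, path, rate: float = 20.0, pathway: str | None = None) -> "EventRaster":
        df = pd.read_csv(path, index_col=0)
        return cls(df.to_numpy(dtype=float), rate=rate, pathway=pathway)

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("events", data=self.events)
            f.attrs["rate"] = self.rate
            if self.pathway is not None:
                f.attrs["pathway"] = self.pathway

    @classmethod
    def from_hdf5(cls, path) -> "EventRaster":
        import h5py

        with h5py.File(path, "r") as f:
            events = f["events"][()]
            rate = float(f.attrs["rate"])
            pathway = f.attrs.get("pathway")
            if pathway is not None:
                pathway = str(pathway)
        return cls(events, rate=rate, pathway=pathway)
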