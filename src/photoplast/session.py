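"""Session container shared by all analysis stages.

A session is a set of simultaneously imaged neurons (raw fluorescence and
dF/F at the imaging frame rate), the trial events produced by the closed
loop, the conditioned-neuron index, and neuron coordinates in the field of
view. dF/F uses F0 = per-neuron median fluorescence across the session.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np

from .bci import TrialEvents

__all__ = ["SessionRecord", "dff_from_raw"]


def dff_from_raw(raw: np.ndarray) -> np.ndarray:
    """dF/F with F0 the per-neuron median across the session."""
    raw = np.asarray(raw, dtype=float)
    f0 = np.median(raw, axis=-1, keepdims=True)
    if np.any(f0 <= 0):
        raise ValueError("non-positive median fluorescence; cannot form dF/F")
    return (raw - f0) / f0


@dataclass
class SessionRecord:
    raw: np.ndarray            # (n_neurons, n_frames) raw fluorescence
    dff: np.ndarray            # (n_neurons, n_frames) dF/F
    frame_rate: float
    events: TrialEvents
    cn_index: int
    positions: np.ndarray | None = None   # (n_neurons, 2) um in FoV
    session_id: str = "session"
    spont_raw: np.ndarray | None = None   # spontaneous period preceding the BCI epoch

    def __post_init__(self) -> None:
        self.raw = np.asarray(self.raw, dtype=float)
        self.dff = np.asarray(self.dff, dtype=float)
        if self.raw.shape != self.dff.shape:
            raise ValueError("raw and dff shapes differ")
        if not (0 <= self.cn_index < self.n_neurons):
            raise ValueError("cn_index out of range")

    @classmethod
    def from_raw(cls, raw, frame_rate, events, cn_index, **kw) -> "SessionRecord":
        return cls(raw=np.asarray(raw, float), dff=dff_from_raw(raw),
                   frame_rate=frame_rate, events=events, cn_index=cn_index, **kw)

    @property
    def n_neurons(self) -> int:
        return self.raw.shape[0]

    @property
    def n_frames(self) -> int:
        return self.raw.shape[1]

    @property
    def times(self) -> np.ndarray:
        """Frame timestamps (s), frame k at k / frame_rate."""
        return np.arange(self.n_frames) / self.frame_rate

    def save(self, path) -> None:
        ev = self.events.to_frame()
        with h5py.File(path, "w") as f:
            f.create_dataset("F_raw", data=self.raw)
            f.create_dataset("dff", data=self.dff)
            f.create_dataset("frame_rate", data=self.frame_rate)
            f.create_dataset("cn_index", data=self.cn_index)
            f.attrs["session_id"] = self.session_id
            if self.positions is not None:
                f.create_dataset("positions", data=self.positions)
            if self.spont_raw is not None:
                f.create_dataset("spont_raw", data=self.spont_raw)
            g = f.create_group("events")
            g.create_dataset("start_s", data=ev["start_s"].to_numpy(float))
            g.create_dataset("reward_s", data=ev["reward_s"].to_numpy(float))
            g.create_dataset("duration_s", data=ev["duration_s"].to_numpy(float))
            g.create_dataset(
                "outcome",
                data=np.array([o.encode() for o in ev["outcome"]]),
            )

    @classmethod
    def load(cls, path) -> "SessionRecord":
        with h5py.File(path, "r") as f:
            events = TrialEvents(
                trial_start_times=f["events/start_s"][()],
                reward_times=f["events/reward_s"][()],
                outcomes=np.array([o.decode() for o in f["events/outcome"][()]],
                                  dtype=object),
                durations=f["events/duration_s"][()],
            )
            return cls(
                raw=f["F_raw"][()],
                dff=f["dff"][()],
                frame_rate=float(f["frame_rate"][()]),
                events=events,
                cn_index=int(f["cn_index"][()]),
                positions=f["positions"][()] if "positions" in f else None,
                spont_raw=f["spont_raw"][()] if "spont_raw" in f else None,
                session_id=f.attrs.get("session_id", "session"),
            )
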