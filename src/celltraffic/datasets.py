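"""Localisation datasets: organ x time curves of fractions of injected cells.

The measured quantity emulates whole-organ radiolabel counts: for each
observable curve and time point, the fraction of the injected cell dose
residing there.  ``Blood`` is the central blood pool only; ``Lungs`` lumps
the pulmonary circuit and the lung blood supply (there is one lung
measurement but two lung organs in the model); every other organ maps to
its own curve (vascular plus interstitial content).

Datasets are serialised as tidy CSV (``curve,time_h,value,stderr``) with a
JSON provenance sidecar recording how they were produced.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .model import Trajectory
from .physiology import CirculatorySystem

__all__ = ["LocalisationDataset", "observables", "curve_organ_map"]

BLOOD_CURVE = "Blood"
LUNG_CURVE = "Lungs"
LUNG_ROLES = ("lung_pulmonary_circuit", "lung_blood_supply")


def curve_organ_map(system: CirculatorySystem) -> dict[str, list[int]]:
    """Observable curve name -> organ indices contributing to it.

    ``Blood`` maps to no organ (it is the central pool).  Lung organs are
    lumped under ``Lungs``; all other organs appear under their own name.
    """
    mapping: dict[str, list[int]] = {BLOOD_CURVE: []}
    lungs = [i for i, o in enumerate(system.organs) if o.role in LUNG_ROLES]
    if lungs:
        mapping[LUNG_CURVE] = lungs
    for i, o in enumerate(system.organs):
        if o.role not in LUNG_ROLES:
            mapping[o.name] = [i]
    return mapping


@dataclass
class LocalisationDataset:
    """Tidy localisation data plus provenance.

    ``data`` columns: ``curve``, ``time_h``, ``value`` and optionally
    ``stderr``.  Times within each curve are strictly increasing.
    ``provenance`` records (when known) the truth parameters, the noise
    configuration, censored organs and any subsampling rule, so noise-free
    datasets are exactly reproducible.
    """

    data: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"curve", "time_h", "value"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"dataset missing columns {sorted(missing)}")
        if (self.data["value"] < 0).any():
            bad = self.data[self.data["value"] < 0].iloc[0]
            raise ValueError(
                f"negative localisation value {bad['value']} "
                f"({bad['curve']} at t = {bad['time_h']} h)"
            )
        for curve, grp in self.data.groupby("curve"):
            t = grp["time_h"].to_numpy()
            if np.any(np.diff(t) <= 0):
                raise ValueError(f"times not strictly increasing for curve {curve!r}")

    # -- access ----------------------------------------------------------

    @property
    def curves(self) -> list[str]:
        return list(dict.fromkeys(self.data["curve"]))

    def curve_frame(self, curve: str) -> pd.DataFrame:
        frame = self.data[self.data["curve"] == curve]
        if frame.empty:
            raise KeyError(f"no curve named {curve!r}")
        return frame

    def times(self, curve: str | None = None) -> np.ndarray:
        if curve is not None:
            return self.curve_frame(curve)["time_h"].to_numpy(dtype=float)
        return np.unique(self.data["time_h"].to_numpy(dtype=float))

    def values(self, curve: str) -> np.ndarray:
        return self.curve_frame(curve)["value"].to_numpy(dtype=float)

    def wide(self) -> pd.DataFrame:
        """Curves as columns on the union time grid (NaN where unmeasured)."""
        return self.data.pivot(index="time_h", columns="curve", values="value")

    def has_initial_row(self) -> bool:
        return bool((self.data["time_h"] == 0.0).any())

    def n_points(self) -> int:
        return len(self.data)

    def copy_with(
        self, data: pd.DataFrame | None = None, **provenance_updates
    ) -> "LocalisationDataset":
        prov = dict(self.provenance)
        prov.update(provenance_updates)
        return LocalisationDataset(
            self.data.copy() if data is None else data.reset_index(drop=True),
            prov,
        )

    # -- serialisation ----------------------------------------------------

    def to_csv(self, path: str | Path) -> None:
        """Write the tidy table and a ``.provenance.json`` sidecar."""
        path = Path(path)
        self.data.to_csv(path, index=False)
        sidecar = path.with_suffix(path.suffix + ".provenance.json")
        with open(sidecar, "w") as fh:
            json.dump(self.provenance, fh, indent=2, default=_jsonify)

    @classmethod
    def read_csv(cls, path: str | Path) -> "LocalisationDataset":
        path = Path(path)
        data = pd.read_csv(path)
        sidecar = path.with_suffix(path.suffix + ".provenance.json")
        provenance = {}
        if sidecar.exists():
            with open(sidecar) as fh:
                provenance = json.load(fh)
        return cls(data, provenance)


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def observables(
    system: CirculatorySystem, trajectory: Trajectory, dose: float = 1.0
) -> LocalisationDataset:
    """Project a trajectory onto the measured localisation curves.

    Fractions of the injected dose: blood pool content, lumped lung
    content, and per-organ vascular plus interstitial content.  When every
    organ is observed the curves sum to 1 at each time.
    """
    n = system.n_organs
    V = system.vascular_volumes
    Vt = system.interstitial_volumes
    contents = (
        trajectory.states[:, 1 : 1 + n] * V + trajectory.states[:, 1 + n :] * Vt
    )  # (T, n) cells per organ
    rows = []
    mapping = curve_organ_map(system)
    for curve, organ_idx in mapping.items():
        if curve == BLOOD_CURVE:
            values = system.blood_pool_volume * trajectory.states[:, 0] / dose
        else:
            values = contents[:, organ_idx].sum(axis=1) / dose
        # solver round-off can leave values a hair below zero
        values = np.where((values > -1e-10) & (values < 0.0), 0.0, values)
        for t, v in zip(trajectory.times, values):
            rows.append({"curve": curve, "time_h": float(t), "value": float(v)})
    data = pd.DataFrame(rows)
    return LocalisationDataset(data, {"dose": dose})
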