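"""Per-organ trafficking kinetics: extravasation probability and return fraction.

Each organ carries two dimensionless parameters:

* ``e`` — the probability that a cell transiting the organ's vasculature
  extravasates into the interstitium rather than returning to circulation,
  so ``0 <= e <= 1``;
* ``mu`` — the return fraction, such that ``e * mu * B * C~`` is the rate at
  which cells leave the interstitium via the lymphatics (``mu > 0``).

Vector convention (fixed everywhere in this package): all ``e`` values in
system organ order, then all ``mu`` values in the same order.  Parameter
names are ``e_<organ>`` and ``mu_<organ>``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .physiology import CirculatorySystem

__all__ = ["KineticParameters"]


@dataclass(frozen=True)
class KineticParameters:
    """Trafficking parameters for every organ of a system.

    ``free_mask`` marks which entries (in ``[e..., mu...]`` order) are
    adjustable during fitting; fixed entries keep their values.
    """

    organ_names: tuple[str, ...]
    e: np.ndarray
    mu: np.ndarray
    free_mask: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        e = np.asarray(self.e, dtype=float)
        mu = np.asarray(self.mu, dtype=float)
        n = len(self.organ_names)
        if e.shape != (n,) or mu.shape != (n,):
            raise ValueError(
                f"expected {n} e and mu values, got shapes {e.shape}, {mu.shape}"
            )
        if np.any(e < 0) or np.any(e > 1):
            bad = [self.organ_names[i] for i in np.flatnonzero((e < 0) | (e > 1))]
            raise ValueError(f"e out of [0, 1] for organs {bad}")
        if np.any(mu <= 0):
            bad = [self.organ_names[i] for i in np.flatnonzero(mu <= 0)]
            raise ValueError(f"mu must be > 0, violated for organs {bad}")
        mask = self.free_mask
        if mask is None:
            mask = np.ones(2 * n, dtype=bool)
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != (2 * n,):
            raise ValueError(f"free_mask must have shape ({2 * n},)")
        object.__setattr__(self, "e", e)
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "free_mask", mask)

    @classmethod
    def unchecked(
        cls, organ_names, e: np.ndarray, mu: np.ndarray, free_mask: np.ndarray
    ) -> "KineticParameters":
        """Skip domain validation (hot loops whose callers enforce bounds)."""
        obj = object.__new__(cls)
        object.__setattr__(obj, "organ_names", organ_names)
        object.__setattr__(obj, "e", e)
        object.__setattr__(obj, "mu", mu)
        object.__setattr__(obj, "free_mask", free_mask)
        return obj

    @classmethod
    def from_vector(
        cls,
        organ_names,
        vector: np.ndarray,
        free_mask: np.ndarray | None = None,
    ) -> "KineticParameters":
        vector = np.asarray(vector, dtype=float)
        n = len(organ_names)
        if vector.shape != (2 * n,):
            raise ValueError(f"parameter vector must have shape ({2 * n},)")
        return cls(tuple(organ_names), vector[:n], vector[n:], free_mask)

    def to_vector(self) -> np.ndarray:
        return np.concatenate([self.e, self.mu])

    @property
    def names(self) -> tuple[str, ...]:
        """Parameter names in vector order."""
        return tuple(f"e_{o}" for o in self.organ_names) + tuple(
            f"mu_{o}" for o in self.organ_names
        )

    @property
    def n_organs(self) -> int:
        return len(self.organ_names)

    def organ_index(self, organ: str) -> int:
        return self.organ_names.index(organ)

    def replace_values(self, vector: np.ndarray) -> "KineticParameters":
        """New parameter set with the same mask and a new ``[e..., mu...]``."""
        return KineticParameters.from_vector(
            self.organ_names, vector, self.free_mask.copy()
        )

    def with_free_mask(self, mask: np.ndarray) -> "KineticParameters":
        return KineticParameters.from_vector(self.organ_names, self.to_vector(), mask)

    def fix_all_e(self) -> "KineticParameters":
        """Freeze every extravasation probability at its current value."""
        mask = self.free_mask.copy()
        mask[: self.n_organs] = False
        return self.with_free_mask(mask)

    def matches_system(self, system: CirculatorySystem) -> bool:
        return self.organ_names == system.names

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, self.to_vector()))
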