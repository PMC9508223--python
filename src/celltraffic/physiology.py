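"""Organ topology of the whole-body circulatory system.

The body is represented as a central blood pool (heart plus large vessels)
feeding a set of organs in parallel.  Each organ has a vascular space that
equilibrates with arterial blood and an interstitial space that cells enter
by extravasation and leave via the lymphatics.  Three wiring features go
beyond the plain parallel layout:

* a *portal system*: splanchnic organs (spleen, stomach, intestine) drain
  venously into the liver instead of straight back to the heart;
* a *lymph node* organ through whose interstitium the lymph of other organs
  may be routed before returning to the heart;
* a *pulmonary circuit* carrying the full cardiac output, modelled as a
  parallel organ whose blood flow equals cardiac output.

Units throughout: volumes in mL, flows in mL/h, time in hours.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "OrganSpec",
    "CirculatorySystem",
    "TopologyError",
    "PhysiologyError",
    "build_system",
    "load_physiology_table",
    "load_topology_config",
    "default_physiology_table",
    "default_topology",
]

ROLES = {
    "generic",
    "lung_pulmonary_circuit",
    "lung_blood_supply",
    "spleen",
    "mesenteric",
    "liver",
    "lymph_node",
}

LYMPH_ROUTES = {"via_lymph_node", "direct_to_heart"}


class PhysiologyError(ValueError):
    """Invalid physiological constants (non-positive volume, bad flow...)."""


class TopologyError(ValueError):
    """Invalid circulatory wiring (unknown portal target, duplicate roles...)."""


@dataclass(frozen=True)
class OrganSpec:
    """A single organ: volumes, blood flow and wiring.

    Parameters
    ----------
    name
        Organ identifier, e.g. ``"Spleen"``.
    vascular_volume
        Volume of the organ's vascular space, mL.
    interstitial_volume
        Volume of the organ's interstitial space, mL.
    blood_flow
        Arterial blood flow to the organ, mL/h.  For the pulmonary circuit
        this is overridden with cardiac output by :func:`build_system` when
        ``lung_pc_flow_mode: cardiac_output``.
    role
        One of ``generic``, ``lung_pulmonary_circuit``, ``lung_blood_supply``,
        ``spleen``, ``mesenteric``, ``liver``, ``lymph_node``.
    portal_target
        Name of the organ (role ``liver``) receiving this organ's venous
        outflow; ``None`` means the outflow returns to the heart.
    lymph_route
        ``via_lymph_node`` or ``direct_to_heart``.
    """

    name: str
    vascular_volume: float
    interstitial_volume: float
    blood_flow: float
    role: str = "generic"
    portal_target: str | None = None
    lymph_route: str = "via_lymph_node"

    def __post_init__(self) -> None:
        if self.vascular_volume <= 0:
            raise PhysiologyError(
                f"organ {self.name!r}: vascular volume must be > 0, "
                f"got {self.vascular_volume}"
            )
        if self.interstitial_volume <= 0:
            raise PhysiologyError(
                f"organ {self.name!r}: interstitial volume must be > 0, "
                f"got {self.interstitial_volume}"
            )
        if self.blood_flow < 0:
            raise PhysiologyError(
                f"organ {self.name!r}: blood flow must be >= 0, "
                f"got {self.blood_flow}"
            )
        if self.role not in ROLES:
            raise PhysiologyError(f"organ {self.name!r}: unknown role {self.role!r}")
        if self.lymph_route not in LYMPH_ROUTES:
            raise TopologyError(
                f"organ {self.name!r}: unknown lymph route {self.lymph_route!r}"
            )


@dataclass(frozen=True)
class CirculatorySystem:
    """A validated whole-body system: blood pool plus organs.

    The state vector convention used by :mod:`celltraffic.model` is
    ``[C_h, C_1 .. C_n, C~_1 .. C~_n]`` (blood-pool concentration, organ
    vascular concentrations, organ interstitial concentrations) with organs
    in the order of :attr:`organs`.
    """

    organs: tuple[OrganSpec, ...]
    blood_pool_volume: float

    def __post_init__(self) -> None:
        if self.blood_pool_volume <= 0:
            raise PhysiologyError(
                f"blood pool volume must be > 0, got {self.blood_pool_volume}"
            )
        names = [o.name for o in self.organs]
        if len(set(names)) != len(names):
            raise TopologyError(f"duplicate organ names in {names}")
        for role in ("lung_pulmonary_circuit", "lung_blood_supply", "lymph_node"):
            if sum(o.role == role for o in self.organs) > 1:
                raise TopologyError(f"more than one organ with role {role!r}")
        livers = {o.name for o in self.organs if o.role == "liver"}
        for o in self.organs:
            if o.portal_target is not None and o.portal_target not in livers:
                raise TopologyError(
                    f"organ {o.name!r}: portal target {o.portal_target!r} "
                    f"is not an organ with role 'liver'"
                )

    # -- indexing helpers -------------------------------------------------

    @property
    def n_organs(self) -> int:
        return len(self.organs)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(o.name for o in self.organs)

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"no organ named {name!r} in system") from None

    def _role_index(self, role: str) -> int | None:
        for i, o in enumerate(self.organs):
            if o.role == role:
                return i
        return None

    @property
    def liver_index(self) -> int | None:
        return self._role_index("liver")

    @property
    def lymph_node_index(self) -> int | None:
        return self._role_index("lymph_node")

    @property
    def lung_pc_index(self) -> int | None:
        return self._role_index("lung_pulmonary_circuit")

    @property
    def lung_bs_index(self) -> int | None:
        return self._role_index("lung_blood_supply")

    @property
    def portal_indices(self) -> tuple[int, ...]:
        return tuple(
            i for i, o in enumerate(self.organs) if o.portal_target is not None
        )

    # -- physiological constants as arrays --------------------------------

    @property
    def vascular_volumes(self) -> np.ndarray:
        return np.array([o.vascular_volume for o in self.organs])

    @property
    def interstitial_volumes(self) -> np.ndarray:
        return np.array([o.interstitial_volume for o in self.organs])

    @property
    def arterial_flows(self) -> np.ndarray:
        """Arterial blood flow per organ (pulmonary circuit included as-is)."""
        return np.array([o.blood_flow for o in self.organs])

    @property
    def cardiac_output(self) -> float:
        """Total systemic blood flow (sum over non-pulmonary-circuit organs)."""
        return float(
            sum(o.blood_flow for o in self.organs if o.role != "lung_pulmonary_circuit")
        )

    @property
    def total_blood_volume(self) -> float:
        """Blood pool plus all organ vascular volumes, mL."""
        return float(self.blood_pool_volume + self.vascular_volumes.sum())

    @property
    def compartment_volumes(self) -> np.ndarray:
        """Volumes in state-vector order ``[V_h, V_o ..., V~_o ...]``."""
        return np.concatenate(
            ([self.blood_pool_volume], self.vascular_volumes, self.interstitial_volumes)
        )

    @property
    def n_states(self) -> int:
        return 1 + 2 * self.n_organs

    def routed_via_lymph_node(self) -> np.ndarray:
        """Boolean mask: organ's lymph passes through the lymph node.

        The lymph node itself, and every organ when no lymph node exists,
        discharge directly to the heart.
        """
        ln = self.lymph_node_index
        mask = np.zeros(self.n_organs, dtype=bool)
        if ln is None:
            return mask
        for i, o in enumerate(self.organs):
            mask[i] = o.lymph_route == "via_lymph_node" and i != ln
        return mask


# ---------------------------------------------------------------------------
# Table / config loading


def _data_path(name: str):
    return importlib.resources.files("celltraffic.data").joinpath(name)


def default_physiology_table() -> pd.DataFrame:
    """Bundled rat physiology: ~20 mL total blood, ~200 mL/h cardiac output."""
    with importlib.resources.as_file(_data_path("rat_physiology.csv")) as p:
        return load_physiology_table(p)


def default_topology() -> dict:
    """Bundled default wiring (portal splanchnic organs, lymph via node)."""
    with importlib.resources.as_file(_data_path("default_topology.yaml")) as p:
        return load_topology_config(p)


def load_physiology_table(path: str | Path) -> pd.DataFrame:
    """Read a physiology CSV with columns
    ``organ,role,V_vasc_mL,V_int_mL,B_mL_per_h`` and one ``blood_pool`` row."""
    table = pd.read_csv(path)
    required = {"organ", "V_vasc_mL", "V_int_mL", "B_mL_per_h"}
    missing = required - set(table.columns)
    if missing:
        raise PhysiologyError(f"physiology table missing columns {sorted(missing)}")
    if "role" not in table.columns:
        table["role"] = "generic"
    return table


def load_topology_config(path: str | Path) -> dict:
    with open(path) as fh:
        config = yaml.safe_load(fh)
    if not isinstance(config, Mapping):
        raise TopologyError(f"topology config {path} is not a mapping")
    return dict(config)


def _normalise_lymph_routing(
    routing, organ_names: Iterable[str]
) -> dict[str, str]:
    """Accept a single route for all organs or a per-organ mapping."""
    organ_names = list(organ_names)
    if routing is None:
        routing = "via_lymph_node"
    if isinstance(routing, str):
        if routing not in LYMPH_ROUTES:
            raise TopologyError(f"unknown lymph routing {routing!r}")
        return {name: routing for name in organ_names}
    routes = {name: "via_lymph_node" for name in organ_names}
    for name, route in dict(routing).items():
        if name not in routes:
            raise TopologyError(f"lymph routing names unknown organ {name!r}")
        if route not in LYMPH_ROUTES:
            raise TopologyError(f"unknown lymph route {route!r} for {name!r}")
        routes[name] = route
    return routes


def build_system(
    physiology_table: pd.DataFrame | str | Path | None = None,
    topology_config: Mapping | str | Path | None = None,
    organ_subset: Sequence[str] | None = None,
) -> CirculatorySystem:
    """Assemble and validate a :class:`CirculatorySystem`.

    Parameters
    ----------
    physiology_table
        DataFrame or CSV path; defaults to the bundled rat table.
    topology_config
        Mapping or YAML path with keys ``portal_organs``, ``lymph_routing``
        and ``lung_pc_flow_mode``; defaults to the bundled wiring.
    organ_subset
        Optional subset of organ names to retain.  Wiring referring to
        excluded organs is dropped (a portal organ whose liver is excluded
        reverts to venous return to the heart).
    """
    if physiology_table is None:
        table = default_physiology_table()
    elif isinstance(physiology_table, (str, Path)):
        table = load_physiology_table(physiology_table)
    else:
        table = physiology_table.copy()

    if topology_config is None:
        config = default_topology()
    elif isinstance(topology_config, (str, Path)):
        config = load_topology_config(topology_config)
    else:
        config = dict(topology_config)

    pool_rows = table[table["organ"] == "blood_pool"]
    if len(pool_rows) != 1:
        raise PhysiologyError("physiology table needs exactly one blood_pool row")
    blood_pool_volume = float(pool_rows["V_vasc_mL"].iloc[0])

    organ_rows = table[table["organ"] != "blood_pool"]
    names = list(organ_rows["organ"])
    if organ_subset is not None:
        subset = list(organ_subset)
        if not subset:
            raise TopologyError("organ subset must not be empty")
        unknown = set(subset) - set(names)
        if unknown:
            raise TopologyError(f"organ subset names unknown organs {sorted(unknown)}")
        organ_rows = organ_rows[organ_rows["organ"].isin(subset)]
        names = list(organ_rows["organ"])

    portal_organs = list(config.get("portal_organs", []))
    routing = _normalise_lymph_routing(config.get("lymph_routing"), names)
    flow_mode = config.get("lung_pc_flow_mode", "cardiac_output")
    if flow_mode not in {"cardiac_output", "table"}:
        raise TopologyError(f"unknown lung_pc_flow_mode {flow_mode!r}")

    roles = dict(zip(organ_rows["organ"], organ_rows["role"]))
    liver_names = [n for n, r in roles.items() if r == "liver"]
    for name in portal_organs:
        if name in roles and not liver_names:
            # portal system configured but the liver is not in this system:
            # the venous outflow reverts to the heart
            pass

    organs = []
    for _, row in organ_rows.iterrows():
        name = row["organ"]
        target = None
        if name in portal_organs:
            if name not in roles:
                raise TopologyError(f"portal organ {name!r} not in physiology table")
            if liver_names:
                target = liver_names[0]
        organs.append(
            OrganSpec(
                name=name,
                vascular_volume=float(row["V_vasc_mL"]),
                interstitial_volume=float(row["V_int_mL"]),
                blood_flow=float(row["B_mL_per_h"]),
                role=str(row["role"]),
                portal_target=target,
                lymph_route=routing[name],
            )
        )

    unknown_portal = set(portal_organs) - set(names)
    if unknown_portal and organ_subset is None:
        raise TopologyError(
            f"portal organs not in physiology table: {sorted(unknown_portal)}"
        )

    system = CirculatorySystem(tuple(organs), blood_pool_volume)

    if flow_mode == "cardiac_output" and system.lung_pc_index is not None:
        i = system.lung_pc_index
        pc = system.organs[i]
        organs = list(system.organs)
        organs[i] = OrganSpec(
            name=pc.name,
            vascular_volume=pc.vascular_volume,
            interstitial_volume=pc.interstitial_volume,
            blood_flow=system.cardiac_output,
            role=pc.role,
            portal_target=pc.portal_target,
            lymph_route=pc.lymph_route,
        )
        system = CirculatorySystem(tuple(organs), blood_pool_volume)

    return system
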