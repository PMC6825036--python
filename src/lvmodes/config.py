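"""Run configuration: schema-validated JSON in, fully resolved model out.

Every block is optional in the file; missing values are filled from the
package defaults and the provenance of each filled value is recorded so a
run manifest can state which numbers were supplied and which were
defaulted.  Unknown keys are rejected.
"""

from __future__ import annotations

import hashlib
import json
from typing import Literal, Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, Field

from .constitutive import ActiveParams, PassiveParams
from .dynamics import CirculationParams, LVModel
from .fibers import FiberArchitecture
from .geometry import ReferenceDomain, make_fixture_geometry
from .modes import ModeBasisSpec, standard_basis

__all__ = ["RunConfig", "load_config", "config_hash", "build_model"]


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GeometryConfig(_Block):
    preset: Literal["axisymmetric", "asymmetric-septal"] = "axisymmetric"
    file: Optional[str] = None          # serialized ReferenceDomain JSON
    a: Optional[float] = None
    mu_in: Optional[float] = None
    mu_out: Optional[float] = None
    nu_up: Optional[float] = None


class ModesConfig(_Block):
    n_q: int = Field(8, ge=1)
    spec: Optional[dict] = None         # explicit term lists, overrides n_q


class MaterialConfig(_Block):
    k_e: float = PassiveParams.k_e
    b_ff: float = PassiveParams.b_ff
    b_xx: float = PassiveParams.b_xx
    b_fx: float = PassiveParams.b_fx
    k_v: float = PassiveParams.k_v


class ActiveConfig(_Block):
    k_a: float = ActiveParams.k_a
    k_av: float = ActiveParams.k_av
    L_s0: float = ActiveParams.L_s0
    L_smax: float = ActiveParams.L_smax
    L_sw: float = ActiveParams.L_sw
    d: float = ActiveParams.d
    T_act: float = ActiveParams.T_act
    t_on: float = ActiveParams.t_on


class CirculationConfig(_Block):
    P_pv: float = CirculationParams.P_pv
    P_sv: float = CirculationParams.P_sv
    R_mv: float = CirculationParams.R_mv
    R_aov: float = CirculationParams.R_aov
    p_steep: float = CirculationParams.p_steep
    R_per: float = CirculationParams.R_per
    C_art: float = CirculationParams.C_art
    P_art_init: float = CirculationParams.P_art_init


class FiberConfig(_Block):
    alpha_endo: float = 60.0
    alpha_epi: float = -60.0


class GridConfig(_Block):
    n_mu: int = Field(5, ge=3)
    n_nu: int = Field(21, ge=5)
    n_phi: int = Field(20, ge=4)


class SolverConfig(_Block):
    n_cycles: int = Field(3, ge=1)
    n_pre: int = Field(1, ge=0)
    steps_per_cycle: int = Field(400, ge=10)
    period: float = Field(0.8, gt=0)
    seed: int = 0


class RunConfig(_Block):
    geometry: GeometryConfig = GeometryConfig()
    modes: ModesConfig = ModesConfig()
    material: MaterialConfig = MaterialConfig()
    active: ActiveConfig = ActiveConfig()
    circulation: CirculationConfig = CirculationConfig()
    fibers: FiberConfig = FiberConfig()
    grid: GridConfig = GridConfig()
    solver: SolverConfig = SolverConfig()

    def provenance(self, raw: dict | None = None):
        """Per-field source: 'file' if supplied, else 'package-default'."""
        raw = raw or {}
        out = {}
        for block, model in self.model_dump().items():
            for key in model:
                src = "file" if key in raw.get(block, {}) else "package-default"
                out[f"{block}.{key}"] = src
        return out


def load_config(path_or_dict) -> tuple[RunConfig, dict]:
    """Validate a JSON config file (or dict); returns (config, provenance)."""
    if isinstance(path_or_dict, dict):
        raw = path_or_dict
    else:
        with open(path_or_dict) as fh:
            raw = json.load(fh)
    cfg = RunConfig.model_validate(raw)
    return cfg, cfg.provenance(raw)


def config_hash(cfg: RunConfig) -> str:
    """Stable short hash of the fully resolved configuration."""
    blob = json.dumps(cfg.model_dump(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def build_model(cfg: RunConfig) -> LVModel:
    """Instantiate the LV model described by a validated configuration."""
    g = cfg.geometry
    if g.file is not None:
        dom = ReferenceDomain.from_json(g.file)
    else:
        kw = {k: getattr(g, k) for k in ("a", "mu_in", "mu_out", "nu_up")
              if getattr(g, k) is not None}
        dom = make_fixture_geometry(g.preset, **kw)
    basis = (ModeBasisSpec.from_dict(cfg.modes.spec) if cfg.modes.spec
             else standard_basis(cfg.modes.n_q))
    return LVModel(
        dom, basis,
        passive=PassiveParams(**cfg.material.model_dump()),
        active=ActiveParams(**cfg.active.model_dump()),
        circ=CirculationParams(**cfg.circulation.model_dump()),
        arch=FiberArchitecture(**cfg.fibers.model_dump()),
        n_mu=cfg.grid.n_mu, n_nu=cfg.grid.n_nu, n_phi=cfg.grid.n_phi,
    )
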