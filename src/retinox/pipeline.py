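"""End-to-end simulation pipeline and condition sweeps.

A run proceeds: generate (or load) the arteriolar tree -> converge the
hemodynamics at the control state -> attach capillary/venule compartment
chains sized by the control terminal flows -> set the Krogh sleeve width
from the capillary density -> optionally re-equilibrate diameters under
flow regulation at the perturbed condition -> solve the arteriolar
Green's-function oxygen field -> propagate oxygen through every
compartment chain -> summarize.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .blood import OxygenParams
from .generate import GeneratorConfig, attach_compartments, generate_arteriolar_tree
from .hemodynamics import (
    FlowSolverConfig,
    iterate_flow,
    propagate_compartment_flows,
)
from .krogh import chain_oxygen, tissue_width_from_density
from .metrics import MetricsReport, build_report
from .network import VascularNetwork
from .oxygen_greens import TissueDomain, solve_greens_field
from .regulation import (
    RegulationParams,
    calibrate_regulation,
    run_to_steady_state,
)

__all__ = ["SimulationConfig", "RunResult", "run_simulation", "sweep"]


@dataclass
class SimulationConfig:
    generator: GeneratorConfig
    m0: float = 2.0  # cm3 O2/100 cm3/min
    capillary_density: float = 500.0  # 1/mm2
    regulation: bool = False
    baseline_m0: float = 2.0  # control condition the tone is calibrated at
    baseline_capillary_density: float = 500.0
    vol_a: float = 0.00115  # cm3
    tissue_spacing: float = 60.0  # µm, arteriolar tissue grid
    tissue_margin: float = 120.0  # µm around the network bounding box
    oxygen: OxygenParams = field(default_factory=OxygenParams)
    flow: FlowSolverConfig = field(default_factory=FlowSolverConfig)
    regulation_params: RegulationParams = field(default_factory=RegulationParams)
    run_greens: bool = True


@dataclass
class RunResult:
    config: SimulationConfig
    network: VascularNetwork
    chains: list
    chain_flows: dict
    tissue_width: float  # µm
    field: object  # OxygenField or None
    chain_results: list
    report: MetricsReport | None
    regulation_summary: object = None


def run_simulation(cfg: SimulationConfig,
                   network: VascularNetwork | None = None) -> RunResult:
    """Run the full pipeline; deterministic given (config, seed)."""
    oxy = replace(cfg.oxygen, m0=cfg.m0)
    net = network.copy() if network is not None else \
        generate_arteriolar_tree(cfg.generator)
    iterate_flow(net, cfg.flow)

    # compartments sized by control-state flows, then fixed
    chains = attach_compartments(net, cfg=cfg.generator)
    d_width = tissue_width_from_density(chains, cfg.vol_a,
                                        cfg.capillary_density)
    reg_summary = None
    if cfg.regulation:
        d_base = tissue_width_from_density(chains, cfg.vol_a,
                                           cfg.baseline_capillary_density)
        oxy_base = replace(cfg.oxygen, m0=cfg.baseline_m0)
        state = calibrate_regulation(net, chains, oxy_base,
                                     cfg.regulation_params, d_base)
        inner_cfg = replace(cfg.flow, linear_solver="direct")
        reg_summary = run_to_steady_state(
            state, net, chains, oxy, cfg.regulation_params,
            flow_cfg=inner_cfg, tissue_width=d_width,
        )
        iterate_flow(net, cfg.flow)  # final converged pass at new diameters

    chain_flows = propagate_compartment_flows(net, chains, cfg.flow)

    field_ = None
    chain_results = []
    report = None
    if cfg.run_greens:
        domain = TissueDomain.from_network(
            net, spacing=cfg.tissue_spacing, margin=cfg.tissue_margin,
            total_volume=cfg.vol_a,
        )
        field_ = solve_greens_field(net, domain, oxy)
        for c in chains:
            p_in = field_.terminal_po2[c.terminal_id]
            hct = net.segment_map()[c.terminal_id].hematocrit
            chain_results.append(chain_oxygen(
                c, p_in, oxy, d_width,
                per_capillary_flow=chain_flows[c.terminal_id].per_capillary_flow,
                hematocrit=hct,
            ))
        report = build_report(
            net, chains, chain_results, field_, oxy.inlet_saturation,
            config_key={
                "m0": cfg.m0,
                "capillary_density": cfg.capillary_density,
                "regulation": cfg.regulation,
                "inlet_saturation": oxy.inlet_saturation,
                "inlet_pressure": net.inlet_pressure,
                "outlet_pressure": net.outlet_pressure,
                "network": cfg.generator.seed if network is None else "external",
            },
        )
    return RunResult(
        config=cfg,
        network=net,
        chains=chains,
        chain_flows=chain_flows,
        tissue_width=d_width,
        field=field_,
        chain_results=chain_results,
        report=report,
        regulation_summary=reg_summary,
    )


def sweep(base: SimulationConfig, vary: str, values,
          regulation_modes=(False,), network: VascularNetwork | None = None):
    """Run the pipeline across a condition sweep.

    ``vary`` is ``"m0"`` or ``"capillary_density"``; each sweep point runs
    the full pipeline and contributes one row of summary metrics.
    """
    if vary not in ("m0", "capillary_density"):
        raise ValueError("vary must be 'm0' or 'capillary_density'")
    if network is None:
        network = generate_arteriolar_tree(base.generator)
    rows = []
    for reg in regulation_modes:
        for v in values:
            cfg = replace(base, regulation=bool(reg), **{vary: float(v)})
            try:
                res = run_simulation(cfg, network=network)
            except Exception as exc:
                raise RuntimeError(
                    f"sweep point {vary}={v}, regulation={reg} failed: {exc}"
                ) from exc
            frac25 = float(np.interp(25.0, res.report.thresholds,
                                     res.report.threshold_curve))
            rows.append({
                vary: float(v),
                "regulation": bool(reg),
                "oef": res.report.oef,
                "mean_tissue_po2": res.report.mean_tissue_po2,
                "fraction_below_25mmHg": frac25,
                "av_saturation_difference": res.report.av_saturation_difference,
                "tissue_width_um": res.tissue_width,
            })
    return rows
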