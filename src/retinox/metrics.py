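"""Network-comparison metrics: oxygen extraction fraction, hypoxic-tissue
threshold curves, pathway-averaged Krogh profiles, and condition sweeps."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MetricsReport",
    "oxygen_extraction_fraction",
    "build_report",
    "compare_networks",
]


def oxygen_extraction_fraction(flows, svo2, sao2: float) -> float:
    """OEF = sum Q_i (SaO2 - SvO2_i) / (Q_total SaO2).

    ``svo2`` are the saturations at the downstream end of the capillaries
    along each pathway; ``flows`` the pathway blood flows.
    """
    q = np.asarray(flows, dtype=float)
    sv = np.asarray(svo2, dtype=float)
    q_total = q.sum()
    if q_total <= 0:
        raise ValueError("total pathway flow must be positive")
    if sao2 <= 0:
        raise ValueError("arterial saturation must be positive")
    return float(np.sum(q * (sao2 - sv)) / (q_total * sao2))


@dataclass
class MetricsReport:
    oef: float
    av_saturation_difference: float  # SaO2 - flow-weighted mean SvO2
    thresholds: np.ndarray  # mmHg
    threshold_curve: np.ndarray  # fraction of arteriolar tissue below
    radial_positions: np.ndarray  # µm from the capillary axis
    mean_radial_profile: np.ndarray  # unweighted pathway mean PO2
    flow_weighted_radial_profile: np.ndarray
    capillary_counts: np.ndarray  # n_C per pathway
    capillary_lengths: np.ndarray  # µm per pathway
    downstream_po2: np.ndarray  # capillary-outlet blood PO2 per pathway
    tissue_edge_po2: np.ndarray  # Krogh outer-edge PO2 per pathway
    pathway_flows: np.ndarray  # nl/min
    mean_tissue_po2: float  # arteriolar tissue mean, mmHg
    config_key: dict = field(default_factory=dict)

    @property
    def length_po2_correlation(self) -> float:
        """Pearson correlation between capillary length and downstream PO2."""
        if len(self.capillary_lengths) < 3:
            return float("nan")
        return float(np.corrcoef(self.capillary_lengths, self.downstream_po2)[0, 1])


def build_report(
    net,
    chains,
    chain_results,
    field_,
    sao2: float,
    thresholds=None,
    config_key: dict | None = None,
) -> MetricsReport:
    """Assemble the comparison metrics from a completed pipeline run."""
    from .oxygen_greens import fraction_below_threshold

    thresholds = np.arange(0.0, 61.0, 1.0) if thresholds is None else \
        np.asarray(thresholds, dtype=float)
    sm = net.segment_map()
    order = [c.terminal_id for c in chains]
    res = {r.terminal_id: r for r in chain_results}
    flows = np.array([abs(sm[t].flow) for t in order])
    svo2 = np.array([res[t].venous_outlet_saturation for t in order])
    down_po2 = np.array([res[t].capillary_outlet_po2 for t in order])
    edge_po2 = np.array([res[t].tissue_edge_po2 for t in order])
    lengths = np.array([c.capillary_length for c in chains])
    counts = np.array([c.n_capillaries for c in chains])

    profiles = np.stack([res[t].profile.po2 for t in order])
    radial = res[order[0]].profile.r
    w = flows / flows.sum()
    curve = fraction_below_threshold(field_, thresholds)
    oef = oxygen_extraction_fraction(flows, svo2, sao2)
    return MetricsReport(
        oef=oef,
        av_saturation_difference=float(sao2 - np.sum(w * svo2)),
        thresholds=thresholds,
        threshold_curve=curve,
        radial_positions=radial,
        mean_radial_profile=profiles.mean(axis=0),
        flow_weighted_radial_profile=(w[:, None] * profiles).sum(axis=0),
        capillary_counts=counts,
        capillary_lengths=lengths,
        downstream_po2=down_po2,
        tissue_edge_po2=edge_po2,
        pathway_flows=flows,
        mean_tissue_po2=float(np.mean(field_.tissue_po2)),
        config_key=dict(config_key or {}),
    )


def compare_networks(report_a: MetricsReport, report_b: MetricsReport) -> dict:
    """Paired metric differences (A minus B) between two runs that share
    every input except the network geometry."""
    keys_a = {k: v for k, v in report_a.config_key.items() if k != "network"}
    keys_b = {k: v for k, v in report_b.config_key.items() if k != "network"}
    if keys_a != keys_b:
        raise ValueError(
            f"runs differ beyond the network: {keys_a} vs {keys_b}"
        )
    curve_diff = report_a.threshold_curve - report_b.threshold_curve
    prof_a, prof_b = report_a.mean_radial_profile, report_b.mean_radial_profile
    sep_wall = float(prof_a[0] - prof_b[0])
    sep_edge = float(prof_a[-1] - prof_b[-1])
    return {
        "oef_diff": report_a.oef - report_b.oef,
        "mean_tissue_po2_diff": report_a.mean_tissue_po2 - report_b.mean_tissue_po2,
        "mean_downstream_po2_diff": float(
            report_a.downstream_po2.mean() - report_b.downstream_po2.mean()
        ),
        "threshold_curve_diff": curve_diff,
        "max_threshold_curve_diff": float(np.max(np.abs(curve_diff))),
        "radial_separation_wall": sep_wall,
        "radial_separation_edge": sep_edge,
        "radial_separation_growth": sep_edge - sep_wall,
        "relative_radial_separation_growth": (
            abs(sep_edge) - abs(sep_wall)
        ) / max(abs(sep_wall), 1e-12),
        "lower_downstream_po2": (
            "A" if report_a.downstream_po2.mean() < report_b.downstream_po2.mean()
            else "B"
        ),
        "higher_oef": "A" if report_a.oef > report_b.oef else "B",
    }


def sweep_to_frame(rows: list[dict]) -> pd.DataFrame:
    return pd.DataFrame(rows)
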