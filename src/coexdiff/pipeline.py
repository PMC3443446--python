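"""End-to-end orchestration: simulate -> preprocess -> DE -> networks -> compare.

Analysis I: at each time point, build one coexpression network per treatment
dose from the *common* DE genes (nodes shared by construction) using the
control + that-dose samples, then compare the pair by topological overlap
(with the rewiring null) and by differential connectivity.

Analysis II: build the larger all-DE-gene network for each dose comparison,
measure the connectivity difference of the common genes between the two
all-gene networks, and intersect the selected genes with the Analysis I
selections at the same time point.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from coexdiff import compare as cmp_mod
from coexdiff import de as de_mod
from coexdiff import io as io_mod
from coexdiff import network as net_mod
from coexdiff import preprocess as pp_mod
from coexdiff.design import StudyDesign, generate_design
from coexdiff.simulate import TruthConfig, simulate_intensities

log = logging.getLogger("coexdiff")


@dataclass
class RunConfig:
    """Every constant of a pipeline run, recorded in the output manifest."""

    doses: tuple[float, ...] = (0.0, 10.0, 100.0)
    times: tuple[float, ...] = (0.0, 3.0, 8.0, 24.0)
    replicates: int = 2
    n_probes: int = 2000
    seed: int = 0
    truth: TruthConfig = field(default_factory=TruthConfig)
    detection_alpha: float = 0.05
    fdr_q: float = 0.10
    net_params: net_mod.NetworkParams = field(default_factory=net_mod.NetworkParams)
    to_threshold: float = 0.1
    conn_T: int = 10
    n_random: int = 1000
    filter_after_normalize: bool = True
    outdir: str | None = None

    def __post_init__(self):
        if isinstance(self.truth, dict):
            self.truth = TruthConfig(**self.truth)
        if isinstance(self.net_params, dict):
            self.net_params = net_mod.NetworkParams(**self.net_params)
        self.doses = tuple(self.doses)
        self.times = tuple(self.times)
        if len(self.doses) != 3:
            raise ValueError("the two-dose-vs-control analysis needs 3 dose levels")

    @property
    def control(self) -> float:
        return min(self.doses)

    @property
    def treatments(self) -> tuple[float, float]:
        trt = sorted(d for d in self.doses if d != self.control)
        return trt[0], trt[1]

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        doc = yaml.safe_load(text) if str(path).endswith((".yml", ".yaml")) else json.loads(text)
        return cls(**doc)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class PreparedData:
    """Simulated + preprocessed inputs shared by both analyses."""

    design: StudyDesign
    raw: pd.DataFrame
    processed: pd.DataFrame
    detection: pd.DataFrame
    truth: object
    glog_params: pp_mod.GlogParams
    de_results: dict          # time -> dict(low=DEComparison, high=..., summary, common)


def prepare(config: RunConfig) -> PreparedData:
    """Simulate, variance-stabilise, normalise, filter and run the DE stage."""
    design = generate_design(config.doses, config.times, config.replicates)
    raw, detection, truth = simulate_intensities(
        design, config.n_probes, config.truth, seed=config.seed
    )
    params = pp_mod.estimate_glog_params(raw, design)
    log.info("g-log parameters: lambda=%.4g alpha=%.4g", params.lam, params.alpha)
    transformed = pp_mod.glog_transform(raw, params)
    normalized = pp_mod.quantile_normalize(transformed)
    if config.filter_after_normalize:
        processed = pp_mod.filter_detection(normalized, detection, config.detection_alpha)
    else:
        kept = pp_mod.filter_detection(transformed, detection, config.detection_alpha)
        processed = pp_mod.quantile_normalize(kept)
    log.info("%d / %d probes pass detection filter", len(processed), len(raw))

    fit = de_mod.fit_cell_means(processed, design)
    low_dose, high_dose = config.treatments
    de_results = {}
    for time in config.times:
        cl = de_mod.dose_contrast(fit, low_dose, time, control=config.control, q=config.fdr_q)
        ch = de_mod.dose_contrast(fit, high_dose, time, control=config.control, q=config.fdr_q)
        summary, common = de_mod.common_sets(cl, ch)
        de_results[time] = {"low": cl, "high": ch, "summary": summary, "common": common}
    return PreparedData(design, raw, processed, detection, truth, params, de_results)


def _dose_network(prep, config, genes, dose, time):
    """Network over ``genes`` from the control + ``dose`` samples at ``time``."""
    cols = prep.design.column_indices(doses=[config.control, dose], times=[time])
    sub = prep.processed.loc[sorted(genes), prep.processed.columns[cols]]
    corr = net_mod.pairwise_pcc(sub)
    return net_mod.build_network(corr, config.net_params), corr


def run_analysis_I(config: RunConfig, prep: PreparedData | None = None) -> dict:
    """Common-DE-gene network pairs: topological overlap + connectivity.

    Returns a report dict keyed by time point; each entry carries the DE
    summary, the pair of networks, the TO table (with rewiring-null
    p-values when ``config.n_random`` >= 2), the low-TO gene set and the
    connectivity-difference table.  Time points whose common set is too
    small to network (< k_low + 1 genes) are skipped with a log entry.
    """
    prep = prep or prepare(config)
    low_dose, high_dose = config.treatments
    report: dict = {"config": config.to_dict(), "times": {}}
    for ti, time in enumerate(config.times):
        entry: dict = {"summary": prep.de_results[time]["summary"]}
        if time == min(config.times):
            entry["caution"] = (
                "earliest time point: responses may reflect initial shock "
                "rather than dose; interpret with caution"
            )
        common = prep.de_results[time]["common"]
        if len(common) < config.net_params.k_low + 1:
            log.warning(
                "T%g: common set of %d genes too small to network; skipped",
                time, len(common),
            )
            entry["skipped"] = True
            report["times"][time] = entry
            continue
        entry["skipped"] = False
        name = _pair_letters(ti)
        net1, corr1 = _dose_network(prep, config, common, low_dose, time)
        net2, corr2 = _dose_network(prep, config, common, high_dose, time)
        entry["names"] = (f"net{name}1", f"net{name}2")
        entry["networks"] = (net1, net2)
        entry["correlations"] = (corr1, corr2)
        if config.n_random >= 2:
            to_table = cmp_mod.to_significance(
                net1, net2, n_random=config.n_random, seed=_stage_seed(config.seed, ti)
            )
        else:
            to_table = cmp_mod.topological_overlap(net1, net2)
        entry["to_table"] = to_table
        low_to, pct = cmp_mod.select_low_to(to_table, config.to_threshold)
        entry["low_to"] = low_to
        entry["low_to_pct"] = pct
        conn = cmp_mod.connectivity_difference(net1, net2, T=config.conn_T)
        entry["conn_diff"] = conn
        entry["conn_counts"] = cmp_mod.selected_counts(conn)
        report["times"][time] = entry
    if config.outdir:
        _write_report(report, config, prefix="analysisI")
    return report


def run_analysis_II(
    config: RunConfig,
    prep: PreparedData | None = None,
    analysis_I: dict | None = None,
) -> dict:
    """All-DE-gene networks: connectivity differences + cross-level intersection."""
    prep = prep or prepare(config)
    analysis_I = analysis_I or run_analysis_I(config, prep)
    low_dose, high_dose = config.treatments
    report: dict = {"times": {}}
    for ti, time in enumerate(config.times):
        entry: dict = {}
        res = prep.de_results[time]
        common = res["common"]
        de_low, de_high = res["low"].de_set, res["high"].de_set
        if len(common) < config.net_params.k_low + 1:
            log.warning("T%g: common set too small; Analysis II skipped", time)
            entry["skipped"] = True
            report["times"][time] = entry
            continue
        entry["skipped"] = False
        netA, _ = _dose_network(prep, config, de_low, low_dose, time)
        netB, _ = _dose_network(prep, config, de_high, high_dose, time)
        entry["names"] = (
            f"network{_letters(ti)[0]}",
            f"network{_letters(ti)[1]}",
        )
        entry["networks"] = (netA, netB)
        conn_all = cmp_mod.connectivity_difference(
            netA, netB, T=config.conn_T, nodes=sorted(common)
        )
        entry["conn_diff_all"] = conn_all
        sel_all = set(conn_all.index[conn_all["selected"]])
        entry["selected_all"] = sel_all

        entry_I = analysis_I["times"][time]
        if entry_I.get("skipped"):
            entry["intersection"] = set()
        else:
            sel_common = set(
                entry_I["conn_diff"].index[entry_I["conn_diff"]["selected"]]
            )
            entry["intersection"] = cmp_mod.cross_level_intersection(sel_all, sel_common)
        report["times"][time] = entry
    if config.outdir:
        _write_report(report, config, prefix="analysisII")
    return report


def _letters(time_index: int) -> tuple[str, str]:
    a = chr(ord("A") + 2 * time_index)
    return a, chr(ord(a) + 1)


def _pair_letters(time_index: int) -> str:
    a, b = _letters(time_index)
    return a + b


def _stage_seed(seed: int, stage: int) -> int:
    return (int(seed) * 1009 + stage) % (2**31 - 1)


def _write_report(report: dict, config: RunConfig, prefix: str) -> None:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"config": config.to_dict(), "files": {}}
    for time, entry in report["times"].items():
        tag = f"{prefix}_T{time:g}"
        if entry.get("skipped"):
            continue
        for key in ("to_table", "conn_diff", "conn_diff_all"):
            if key in entry:
                path = outdir / f"{tag}_{key}.tsv"
                io_mod.write_table(entry[key], path)
                manifest["files"][path.name] = io_mod.file_checksum(path)
        for key in ("low_to", "selected_all", "intersection"):
            if key in entry:
                path = outdir / f"{tag}_{key}.txt"
                io_mod.write_gene_set(entry[key], path)
                manifest["files"][path.name] = io_mod.file_checksum(path)
        if "networks" in entry:
            for net, name in zip(entry["networks"], entry["names"]):
                path = outdir / f"{tag}_{name}.tsv"
                io_mod.write_network(net, path)
                manifest["files"][path.name] = io_mod.file_checksum(path)
    io_mod.write_json(manifest, outdir / f"{prefix}_manifest.json")
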