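"""Synthetic expression data with known ground truth.

The generator emulates a two-colour-free bead-array experiment: raw probe
intensities follow the two-component measurement-error model

    y_ij = alpha_true + mu_ij * exp(eta_ij) + eps_ij,
    eta ~ N(0, sigma_eta^2),  eps ~ N(0, sigma_eps^2),

i.e. an additive background plus multiplicative (lognormal) and additive
Gaussian noise — exactly the error family the generalised-log transform
stabilises.  The latent signal mu_ij combines

* a per-probe lognormal baseline,
* planted differential-expression shifts for the sample's (dose, time) cell,
  expressed in g-log (natural-log) units, and
* latent-factor coexpression modules: each module is driven by one standard
  normal factor per sample, and member genes load on it on the log scale.
  In the "rewired" dose condition a chosen subset of module genes loads on a
  *different* factor, so their coexpression neighbourhood changes between
  conditions while their marginal behaviour does not.

Everything planted is recorded in a :class:`GroundTruth` so downstream
recovery (DE calls, low-topological-overlap genes) can be scored.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from coexdiff.design import StudyDesign


@dataclass
class TruthConfig:
    """Knobs of the generative model.

    Intensity units are arbitrary fluorescence counts; effect sizes and
    module loadings act on the natural-log scale of the latent signal.
    Signals (DE shifts, module membership) are planted only in probes whose
    baseline sits above the median expressed intensity: effects are
    specified on the g-log scale, and only well-expressed probes realise a
    multiplicative shift as the intended g-log shift (near-background
    probes would confound effect size with detectability).
    """

    n_de_specific: int = 100     # dose-specific DE probes per (dose>0, time)
    n_de_shared: int = 40        # extra shared-DE probes (beyond module genes)
    effect_size: float = 1.5     # |shift| in g-log units, sign random per gene
    n_modules: int = 8
    module_size: int = 20
    frac_rewired: float = 0.15   # fraction of module genes rewired at high dose
    frac_unexpressed: float = 0.1
    alpha_true: float = 50.0     # additive background
    sigma_eta: float = 0.3       # multiplicative noise SD (log scale)
    sigma_eps: float = 30.0      # additive noise SD (intensity scale)
    baseline_log_mean: float = 5.5
    baseline_log_sd: float = 1.2
    module_loading: float = 0.8
    factor_replicate_sd: float = 0.3  # per-sample jitter around the cell factor
    signal_baseline_quantile: float = 0.5  # plant signals above this baseline quantile
    de_times: tuple[float, ...] | None = None   # default: every time level
    plant_de: bool = True
    plant_modules: bool = True

    def __post_init__(self):
        if self.sigma_eta < 0 or self.sigma_eps < 0:
            raise ValueError("noise SDs must be non-negative")
        if not 0 <= self.frac_unexpressed < 1:
            raise ValueError("frac_unexpressed must be in [0, 1)")
        if not 0 <= self.frac_rewired <= 1:
            raise ValueError("frac_rewired must be in [0, 1]")


@dataclass
class GroundTruth:
    """What was planted: DE shifts, module wiring, rewired genes, noise."""

    de_genes: dict = field(default_factory=dict)       # (dose, time) -> {probe: shift}
    module_assignment: dict = field(default_factory=dict)  # condition -> {probe: module}
    rewired_genes: list = field(default_factory=list)
    error_params: dict = field(default_factory=dict)
    unexpressed: list = field(default_factory=list)

    def __post_init__(self):
        conds = list(self.module_assignment)
        if len(conds) >= 2:
            shared = set(self.module_assignment[conds[0]])
            for c in conds[1:]:
                shared &= set(self.module_assignment[c])
            missing = set(self.rewired_genes) - shared
            if missing:
                raise ValueError(
                    f"rewired genes absent from some condition's module map: {sorted(missing)[:5]}"
                )

    def to_json(self, path) -> None:
        doc = {
            "de_genes": {
                f"{d}|{t}": shifts for (d, t), shifts in self.de_genes.items()
            },
            "module_assignment": self.module_assignment,
            "rewired_genes": self.rewired_genes,
            "error_params": self.error_params,
            "unexpressed": self.unexpressed,
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            doc = json.load(fh)
        de = {}
        for key, shifts in doc["de_genes"].items():
            d, t = key.split("|")
            de[(float(d), float(t))] = shifts
        return cls(
            de_genes=de,
            module_assignment=doc["module_assignment"],
            rewired_genes=doc["rewired_genes"],
            error_params=doc["error_params"],
            unexpressed=doc["unexpressed"],
        )


def simulate_intensities(
    design: StudyDesign,
    n_probes: int,
    config: TruthConfig | None = None,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Simulate a raw intensity matrix, detection p-values and ground truth.

    Returns ``(intensities, detection, truth)`` where both frames are
    probe-by-sample with probe ids ``P000001`` ... as the index and the
    design's sample ids as columns.  The rewired module wiring applies to
    samples at the *highest* dose level; all other doses share the base
    wiring, mirroring a design where control and low-dose tissue respond
    alike and the high dose reorganises coexpression.
    """
    cfg = config or TruthConfig()
    if n_probes < 10:
        raise ValueError("n_probes must be >= 10")
    if cfg.plant_modules and cfg.n_modules * cfg.module_size > n_probes:
        raise ValueError("module genes exceed n_probes")
    rng = np.random.default_rng(seed)

    probes = [f"P{i + 1:06d}" for i in range(n_probes)]
    n_samples = design.n_samples
    conditions = design.conditions()

    n_unexp = int(round(cfg.frac_unexpressed * n_probes))
    unexp_idx = rng.choice(n_probes, size=n_unexp, replace=False)
    expressed = np.ones(n_probes, dtype=bool)
    expressed[unexp_idx] = False

    baseline = np.zeros(n_probes)
    baseline[expressed] = np.exp(
        rng.normal(cfg.baseline_log_mean, cfg.baseline_log_sd, expressed.sum())
    )

    # log-scale latent effects accumulate here
    log_shift = np.zeros((n_probes, n_samples))

    # signals go into well-expressed probes (baseline above the chosen quantile)
    if expressed.any():
        cutoff = np.quantile(baseline[expressed], cfg.signal_baseline_quantile)
    else:
        cutoff = np.inf
    eligible = np.flatnonzero(expressed & (baseline >= cutoff))
    rng.shuffle(eligible)
    cursor = 0

    def _take(k: int) -> np.ndarray:
        nonlocal cursor
        if cursor + k > eligible.size:
            raise ValueError(
                "not enough well-expressed probes for the requested planted "
                f"structure (need {cursor + k}, have {eligible.size})"
            )
        out = eligible[cursor : cursor + k]
        cursor += k
        return out

    # --- planted coexpression modules -------------------------------------
    module_assignment: dict[str, dict[str, int]] = {}
    rewired: list[str] = []
    mod_genes = np.array([], dtype=int)
    if cfg.plant_modules:
        n_mod_genes = cfg.n_modules * cfg.module_size
        if n_mod_genes > n_probes:
            raise ValueError("module genes exceed n_probes")
        mod_genes = _take(n_mod_genes)
        base = {
            probes[g]: int(m)
            for m, block in enumerate(np.split(mod_genes, cfg.n_modules))
            for g in block
        }
        rewired_map = dict(base)
        n_rew = int(round(cfg.frac_rewired * n_mod_genes))
        if cfg.n_modules >= 2 and n_rew > 0:
            rew_genes = rng.choice(mod_genes, size=n_rew, replace=False)
            for g in rew_genes:
                p = probes[g]
                others = [m for m in range(cfg.n_modules) if m != base[p]]
                rewired_map[p] = int(rng.choice(others))
                rewired.append(p)
        module_assignment = {"base": base, "rewired": rewired_map}

        # hierarchical factors: one level per design cell, jitter per sample
        cell_ids = {c: k for k, c in enumerate(design.cell_indices())}
        cell_factors = rng.normal(0.0, 1.0, (cfg.n_modules, len(cell_ids)))
        jitter = rng.normal(0.0, cfg.factor_replicate_sd, (cfg.n_modules, n_samples))
        factors = np.empty((cfg.n_modules, n_samples))
        for j, (d, t, _) in enumerate(conditions):
            factors[:, j] = cell_factors[:, cell_ids[(d, t)]] + jitter[:, j]
        high_dose = max(design.doses)
        probe_pos = {p: i for i, p in enumerate(probes)}
        for j, (dose, _, _) in enumerate(conditions):
            wiring = rewired_map if dose == high_dose else base
            for p, m in wiring.items():
                log_shift[probe_pos[p], j] += cfg.module_loading * factors[m, j]

    # --- planted DE --------------------------------------------------------
    # Module genes and a pool of extra genes respond at *both* treatment
    # doses (the shared response that makes the common-DE sets non-trivial);
    # each (dose, time) additionally gets its own dose-specific responders.
    de_genes: dict[tuple[float, float], dict[str, float]] = {}
    if cfg.plant_de:
        de_times = cfg.de_times if cfg.de_times is not None else design.times
        control = min(design.doses)
        treatments = [d for d in design.doses if d != control]
        shared_idx = np.concatenate([mod_genes, _take(cfg.n_de_shared)])
        specific_idx = {d: _take(cfg.n_de_specific) for d in treatments}
        for time in de_times:
            cols_by_dose = {
                d: design.column_indices(doses=[d], times=[time]) for d in treatments
            }
            shared_signs = rng.choice([-1.0, 1.0], size=shared_idx.size)
            for dose in treatments:
                de_genes[(dose, time)] = {}
                for g, s in zip(shared_idx, shared_signs):
                    shift = float(s * cfg.effect_size)
                    log_shift[g, cols_by_dose[dose]] += shift
                    de_genes[(dose, time)][probes[g]] = shift
                signs = rng.choice([-1.0, 1.0], size=cfg.n_de_specific)
                for g, s in zip(specific_idx[dose], signs):
                    shift = float(s * cfg.effect_size)
                    log_shift[g, cols_by_dose[dose]] += shift
                    de_genes[(dose, time)][probes[g]] = shift

    # --- two-component measurement error -----------------------------------
    mu = baseline[:, None] * np.exp(log_shift)
    eta = (
        rng.normal(0.0, cfg.sigma_eta, (n_probes, n_samples))
        if cfg.sigma_eta > 0
        else np.zeros((n_probes, n_samples))
    )
    eps = (
        rng.normal(0.0, cfg.sigma_eps, (n_probes, n_samples))
        if cfg.sigma_eps > 0
        else np.zeros((n_probes, n_samples))
    )
    y = cfg.alpha_true + mu * np.exp(eta) + eps

    detection = np.empty((n_probes, n_samples))
    detection[expressed] = rng.uniform(0.0, 0.05, (int(expressed.sum()), n_samples))
    detection[~expressed] = rng.uniform(0.05, 1.0, (n_unexp, n_samples))

    cols = list(design.sample_ids)
    intensities = pd.DataFrame(y, index=probes, columns=cols)
    det = pd.DataFrame(detection, index=probes, columns=cols)
    truth = GroundTruth(
        de_genes=de_genes,
        module_assignment=module_assignment,
        rewired_genes=sorted(rewired),
        error_params={
            "alpha_true": cfg.alpha_true,
            "sigma_eta": cfg.sigma_eta,
            "sigma_eps": cfg.sigma_eps,
        },
        unexpressed=sorted(probes[i] for i in unexp_idx),
    )
    return intensities, det, truth


def truth_report(truth: GroundTruth) -> dict:
    """Summarise planted structure: DE counts per cell, module sizes, rewired list.

    Returns a dict with a ``de_counts`` DataFrame (dose, time, n_de), a
    ``module_sizes`` DataFrame per condition, and the ``rewired_genes`` list.
    """
    de_rows = [
        {"dose_cGy": d, "time_h": t, "n_de": len(shifts)}
        for (d, t), shifts in sorted(truth.de_genes.items())
    ]
    de_counts = pd.DataFrame(de_rows, columns=["dose_cGy", "time_h", "n_de"])

    mod_rows = []
    for cond, mapping in truth.module_assignment.items():
        sizes = pd.Series(list(mapping.values())).value_counts().sort_index()
        for mod, size in sizes.items():
            mod_rows.append({"condition": cond, "module": mod, "size": int(size)})
    module_sizes = pd.DataFrame(mod_rows, columns=["condition", "module", "size"])

    return {
        "de_counts": de_counts,
        "module_sizes": module_sizes,
        "rewired_genes": list(truth.rewired_genes),
        "n_unexpressed": len(truth.unexpressed),
    }
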