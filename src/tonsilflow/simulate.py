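"""Synthetic tonsillar B-cell scRNA-seq generator with planted ground truth.

The generator emulates the statistical structure the downstream pipeline
assumes: multi-donor negative-binomial counts over ~15-25 discrete B-cell
states, a continuous germinal-center-to-antibody-secreting-cell (GC->ASC)
differentiation axis on a designated subset of states, planted TF->target
regulons whose activity is state-specific or rises/falls along the
continuum, and QC-failing artifact cells (high mitochondrial fraction, high
dissociation signature, low gene count, T-cell contaminants).

Count model
-----------
For cell c and gene g the expected count is ``mu_gc = L_c * p_gc`` where
``L_c`` is a log-normal library size and ``p_gc = softmax_g(eta_gc)`` with

    eta_gc = log(base_g) + state_effect + donor_effect
             + sum_t activity_t(c) * beta * w_gt + continuum_effect(t_c)

Counts are NB with mean/dispersion parameterization ``Var = mu + mu^2/theta``
(``nb_dispersion = theta``); ``theta = inf`` gives the Poisson limit.
Rising/falling continuum profiles are scaled logistic curves in the latent
time ``t ~ U[0,1]``.

Designated gene blocks (mitochondrial ``MT-``, dissociation ``DSG``,
T-cell markers CD3D/IL32/CD2, partition markers CCR7/CD38/PRDM1, chemokines
CCL4/CCL3, immunoglobulin light chains IGKC/IGLC*) let the QC and
annotation stages point their gene-list inputs at the synthetic universe.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
import yaml

from .datatypes import CountMatrix, RegulonSet
from .io import write_gmt, write_tenx_directory

__all__ = ["SimConfig", "SimTruth", "simulate_regulons", "simulate_counts",
           "write_truth", "write_simulation"]

MITO_PREFIX = "MT-"
DISSOC_PREFIX = "DSG"
TCELL_MARKERS = ("CD3D", "IL32", "CD2")
PARTITION_MARKERS = ("CCR7", "CD38", "PRDM1")
CHEMOKINES = ("CCL4", "CCL3")
IG_GENES = ("IGKC", "IGLC1", "IGLC2")
# named members of the rising (ASC) and falling (GC) programs, for realism
ASC_PROGRAM_NAMED = ("XBP1", "MZB1", "JCHAIN", "IRF4")
GC_PROGRAM_NAMED = ("IGHM", "IRF8", "SPIB", "BACH2")

ARTIFACT_KINDS = ("low-gene", "high-mito", "high-dissoc", "t-contaminant")


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Defaults emulate the study design the pipeline targets: 3 donors,
    ~15-25 states including an activated-chemokine state, a 4-state GC->ASC
    continuum, moderate NB overdispersion and a log-scale donor effect.
    """

    n_donors: int = 3
    cells_per_donor: int = 700
    n_genes: int = 1500
    n_states: int = 18
    n_tfs: int = 12
    targets_per_tf: int = 30
    regulon_overlap_fraction: float = 0.1
    continuum_states: tuple = ("GC1", "GC2", "GC3", "ASC1")
    nb_dispersion: float = 10.0
    batch_sd: float = 0.2
    artifact_fractions: dict = field(
        default_factory=lambda: {k: 0.02 for k in ARTIFACT_KINDS}
    )
    seed: int = 0
    # effect sizes (natural-log scale)
    state_effect_mean: float = 1.2
    state_effect_sd: float = 0.4
    state_de_fraction: float = 0.08
    continuum_amplitude: float = 2.0
    tf_effect: float = 1.5
    n_continuum_genes: int = 60  # direct rising + direct falling genes each
    mean_library_size: float = 2500.0
    library_sd_log: float = 0.35
    plant_chemokine_tfs: bool = True

    def __post_init__(self) -> None:
        for name in ("n_donors", "cells_per_donor", "n_genes", "n_states",
                     "n_tfs", "targets_per_tf"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0 <= self.regulon_overlap_fraction <= 1:
            raise ValueError("regulon_overlap_fraction must be in [0, 1]")
        for k, v in self.artifact_fractions.items():
            if k not in ARTIFACT_KINDS:
                raise ValueError(f"unknown artifact kind {k!r}")
            if not 0 <= v <= 1:
                raise ValueError("artifact fractions must be in [0, 1]")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive (inf = Poisson)")
        if self.batch_sd < 0:
            raise ValueError("batch_sd must be non-negative")
        self.continuum_states = tuple(self.continuum_states)
        if len(self.continuum_states) + 1 > self.n_states and self.continuum_states:
            raise ValueError("continuum_states must leave room for discrete states")

    @property
    def state_names(self) -> list:
        """All state IDs; continuum states come last, in path order."""
        n_disc = self.n_states - len(self.continuum_states)
        disc = []
        if n_disc >= 1:
            disc.append("ACTCK")  # activated chemokine-coexpressing state
        disc += [f"NGC{i:02d}" for i in range(1, n_disc)]
        return disc + list(self.continuum_states)

    @property
    def tf_names(self) -> list:
        return [f"TF{i:02d}" for i in range(1, self.n_tfs + 1)]

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["continuum_states"] = list(self.continuum_states)
        return d

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


@dataclass
class SimTruth:
    """Planted ground truth accompanying a simulated count matrix."""

    cells: pd.DataFrame  # index barcode; columns donor, state, latent_t, artifact
    regulons_true: RegulonSet
    gene_dynamics: dict  # gene -> {rising, falling, flat} (direct continuum genes)
    tf_dynamics: dict  # tf -> {rising, falling, flat} along the continuum
    tf_active_state: dict  # tf -> state name or None (state-specific TFs)
    library_sizes: np.ndarray

    @property
    def state_label(self) -> pd.Series:
        return self.cells["state"]

    @property
    def latent_pseudotime(self) -> pd.Series:
        return self.cells["latent_t"]

    @property
    def artifact_flag(self) -> pd.Series:
        return self.cells["artifact"]


def build_gene_universe(config: SimConfig) -> tuple[np.ndarray, dict]:
    """Gene IDs plus a block map naming the designated gene groups."""
    n_mito, n_dissoc = 10, 15
    named = (
        [f"{MITO_PREFIX}G{i:02d}" for i in range(1, n_mito + 1)]
        + [f"{DISSOC_PREFIX}{i:02d}" for i in range(1, n_dissoc + 1)]
        + list(TCELL_MARKERS) + list(PARTITION_MARKERS) + list(CHEMOKINES)
        + list(IG_GENES) + list(ASC_PROGRAM_NAMED) + list(GC_PROGRAM_NAMED)
        + config.tf_names
    )
    n_generic = config.n_genes - len(named)
    if n_generic < config.n_tfs * config.targets_per_tf // 2:
        raise ValueError("n_genes too small for the designated blocks and regulons")
    generic = [f"G{i:04d}" for i in range(1, n_generic + 1)]
    genes = np.array(named + generic, dtype=object)
    blocks = {
        "mito": [g for g in genes if g.startswith(MITO_PREFIX)],
        "dissociation": [g for g in genes if g.startswith(DISSOC_PREFIX)],
        "tcell": list(TCELL_MARKERS),
        "partition": list(PARTITION_MARKERS),
        "chemokine": list(CHEMOKINES),
        "ig": list(IG_GENES),
        "asc_named": list(ASC_PROGRAM_NAMED),
        "gc_named": list(GC_PROGRAM_NAMED),
        "tf": config.tf_names,
        "generic": generic,
    }
    return genes, blocks


def simulate_regulons(config: SimConfig) -> RegulonSet:
    """Plant TF->target regulons with controlled pairwise overlap.

    Every TF receives exactly ``targets_per_tf`` targets: a shared core of
    ``round(overlap * targets_per_tf)`` genes common to all TFs plus a
    private disjoint remainder, so each pairwise intersection equals the
    core size.  With ``plant_chemokine_tfs`` the first three TFs swap two
    private targets for the chemokine genes CCL4 and CCL3 (and only those
    TFs ever target a chemokine).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    _, blocks = build_gene_universe(config)
    pool = list(blocks["generic"])
    k = config.targets_per_tf
    core_size = int(round(config.regulon_overlap_fraction * k))
    need = core_size + config.n_tfs * (k - core_size)
    if need > len(pool):
        raise ValueError(
            f"infeasible regulon configuration: need {need} generic genes, have {len(pool)}"
        )
    order = rng.permutation(len(pool))
    pool = [pool[i] for i in order]
    core = pool[:core_size]
    rest = pool[core_size:]
    regulons = {}
    plant = config.plant_chemokine_tfs and config.n_tfs >= 3
    for i, tf in enumerate(config.tf_names):
        private = rest[i * (k - core_size): (i + 1) * (k - core_size)]
        targets = core + private
        if plant and i < 3:
            targets = targets[:-2] + list(CHEMOKINES)
        weights = rng.uniform(0.5, 1.0, size=len(targets))
        regulons[tf] = {g: float(w) for g, w in zip(targets, weights)}
    return RegulonSet(regulons, provenance="ground-truth")


def _assign_tf_roles(config: SimConfig, rng) -> tuple[dict, dict]:
    """Split TFs into chemokine/state-specific vs rising/falling roles."""
    tf_dyn: dict = {}
    tf_state: dict = {}
    names = config.tf_names
    states = config.state_names
    disc = [s for s in states if s not in config.continuum_states]
    i = 0
    if config.plant_chemokine_tfs and config.n_tfs >= 3 and "ACTCK" in disc:
        for tf in names[:3]:
            tf_dyn[tf] = "flat"
            tf_state[tf] = "ACTCK"
        i = 3
    remaining = names[i:]
    # alternate rising / falling for the first 2/3, state-specific for the rest
    n_dyn = (2 * len(remaining)) // 3
    for j, tf in enumerate(remaining):
        if config.continuum_states and j < n_dyn:
            tf_dyn[tf] = "rising" if j % 2 == 0 else "falling"
            tf_state[tf] = None
        else:
            tf_dyn[tf] = "flat"
            tf_state[tf] = str(rng.choice(disc)) if disc else None
    return tf_dyn, tf_state


def _logistic(t, mid, steep):
    return 1.0 / (1.0 + np.exp(-(t - mid) / steep))


def simulate_counts(config: SimConfig, return_rates: bool = False):
    """Simulate the full multi-donor count matrix plus ground truth.

    Returns ``(CountMatrix, SimTruth)`` or, with ``return_rates``, an
    additional dense genes x cells matrix of the planted NB means ``mu``
    (artifact distortions excluded).
    """
    ss = np.random.SeedSequence([config.seed, 202])
    rng = np.random.default_rng(ss)
    genes, blocks = build_gene_universe(config)
    n_genes = len(genes)
    gidx = {g: i for i, g in enumerate(genes)}
    states = config.state_names
    cont = list(config.continuum_states)
    n_cells = config.n_donors * config.cells_per_donor

    # --- cell frame: donor, state, latent t -------------------------------
    donor = np.repeat([f"donor{d+1}" for d in range(config.n_donors)],
                      config.cells_per_donor)
    is_cont = rng.random(n_cells) < (len(cont) / len(states)) if cont else np.zeros(n_cells, bool)
    latent_t = np.full(n_cells, np.nan)
    state = np.empty(n_cells, dtype=object)
    t_draw = rng.random(n_cells)
    disc_states = [s for s in states if s not in cont]
    disc_draw = rng.integers(0, max(len(disc_states), 1), size=n_cells)
    for i in range(n_cells):
        if is_cont[i]:
            latent_t[i] = t_draw[i]
            state[i] = cont[min(int(t_draw[i] * len(cont)), len(cont) - 1)]
        else:
            state[i] = disc_states[disc_draw[i]] if disc_states else cont[0]

    # --- gene baseline ----------------------------------------------------
    base = rng.gamma(0.6, 1.0, size=n_genes) + 1e-6
    base /= base.sum()

    def _set_block_mass(names, mass):
        ii = [gidx[g] for g in names]
        other = base[ii].sum()
        if other > 0:
            base[ii] *= mass / other

    _set_block_mass(blocks["mito"], 0.015)
    _set_block_mass(blocks["dissociation"], 0.010)
    _set_block_mass(blocks["tcell"], 3e-6)
    _set_block_mass(blocks["ig"], 0.010)
    _set_block_mass(blocks["chemokine"], 2e-4)
    _set_block_mass(blocks["partition"], 1e-3)
    base /= base.sum()
    log_base = np.log(base)

    # --- state differential expression ------------------------------------
    state_eff = {s: np.zeros(n_genes) for s in states}
    generic_idx = np.array([gidx[g] for g in blocks["generic"]])
    n_de = max(3, int(config.state_de_fraction * len(generic_idx)))
    for s in states:
        de = rng.choice(generic_idx, size=n_de, replace=False)
        lfc = rng.normal(config.state_effect_mean, config.state_effect_sd, size=n_de)
        state_eff[s][de] += lfc
    # partition markers (CCR7+CD38- non-GC; CD38+PRDM1- GC; CD38+PRDM1+ ASC)
    for s in states:
        if s in cont:
            state_eff[s][gidx["CD38"]] += 2.5
            if s == cont[-1]:
                state_eff[s][gidx["PRDM1"]] += 1.0  # also rises with t below
        else:
            state_eff[s][gidx["CCR7"]] += 2.5
    # chemokine state: CCL4/CCL3 via its three planted TFs (activity below)

    # --- regulons and TF roles --------------------------------------------
    regulons = simulate_regulons(config)
    tf_dyn, tf_state = _assign_tf_roles(config, rng)

    # --- direct continuum genes -------------------------------------------
    gene_dyn: dict = {}
    avail = [g for g in blocks["generic"]
             if all(g not in regulons.regulons[tf] for tf in regulons.regulons)]
    rng.shuffle(avail)
    n_dir = min(config.n_continuum_genes, len(avail) // 2)
    rising_genes = avail[:n_dir] + list(ASC_PROGRAM_NAMED) + ["PRDM1"]
    falling_genes = avail[n_dir:2 * n_dir] + list(GC_PROGRAM_NAMED)
    for g in rising_genes:
        gene_dyn[g] = "rising"
    for g in falling_genes:
        gene_dyn[g] = "falling"
    mid = {g: rng.uniform(0.3, 0.7) for g in list(rising_genes) + list(falling_genes)}
    steep = {g: rng.uniform(0.08, 0.15) for g in mid}
    amp = {g: config.continuum_amplitude * rng.uniform(0.8, 1.2) for g in mid}
    # PRDM1 is a terminal ASC marker: switch on late and sharply so the
    # CCR7/CD38/PRDM1 partition rule separates GC from ASC clusters
    mid["PRDM1"], steep["PRDM1"], amp["PRDM1"] = 0.85, 0.04, 3.0

    # --- donor effects -----------------------------------------------------
    donor_names = sorted(set(donor))
    donor_eff = {d: rng.normal(0.0, config.batch_sd, size=n_genes)
                 for d in donor_names}

    # --- TF activity per cell ----------------------------------------------
    tf_activity = np.zeros((config.n_tfs, n_cells))
    tf_mid = {tf: rng.uniform(0.35, 0.65) for tf in config.tf_names}
    for ti, tf in enumerate(config.tf_names):
        if tf_dyn[tf] == "rising":
            on = is_cont
            tf_activity[ti, on] = _logistic(latent_t[on], tf_mid[tf], 0.12)
        elif tf_dyn[tf] == "falling":
            on = is_cont
            tf_activity[ti, on] = 1.0 - _logistic(latent_t[on], tf_mid[tf], 0.12)
        elif tf_state.get(tf):
            tf_activity[ti, state == tf_state[tf]] = 1.0

    # --- assemble eta -> softmax -> counts ---------------------------------
    eta = np.tile(log_base[:, None], (1, n_cells))
    for s in states:
        cols = state == s
        if cols.any():
            eta[:, cols] += state_eff[s][:, None]
    for d in donor_names:
        cols = donor == d
        eta[:, cols] += donor_eff[d][:, None]
    cont_cols = np.where(is_cont)[0]
    for g in mid:
        prof = _logistic(latent_t[cont_cols], mid[g], steep[g])
        if gene_dyn[g] == "falling":
            prof = 1.0 - prof
        eta[gidx[g], cont_cols] += amp[g] * prof
    w_mat = np.zeros((config.n_tfs, n_genes))
    for ti, tf in enumerate(config.tf_names):
        for g, w in regulons.regulons[tf].items():
            w_mat[ti, gidx[g]] = w
        w_mat[ti, gidx[tf]] = 1.0  # the TF's own transcript tracks its activity
    eta += config.tf_effect * (w_mat.T @ tf_activity)

    eta -= eta.max(axis=0, keepdims=True)
    p = np.exp(eta)
    p /= p.sum(axis=0, keepdims=True)

    lib = rng.lognormal(np.log(config.mean_library_size), config.library_sd_log,
                        size=n_cells)
    mu = p * lib[None, :]
    counts = _sample_nb(rng, mu, config.nb_dispersion)

    # --- artifacts ----------------------------------------------------------
    artifact = np.array(["none"] * n_cells, dtype=object)
    free = rng.permutation(n_cells)
    pos = 0
    for kind in ARTIFACT_KINDS:
        n_k = int(round(config.artifact_fractions.get(kind, 0.0) * n_cells))
        chosen = free[pos:pos + n_k]
        pos += n_k
        artifact[chosen] = kind
        for c in chosen:
            _apply_artifact(rng, counts, c, kind, blocks, gidx, mu, config)

    barcodes = np.array(
        [f"{donor[i]}:CELL{i:05d}" for i in range(n_cells)], dtype=object
    )
    cm = CountMatrix(sp.csr_matrix(counts), genes, barcodes, donor)
    cells = pd.DataFrame(
        {"donor": donor, "state": state, "latent_t": latent_t, "artifact": artifact},
        index=barcodes,
    )
    truth = SimTruth(cells, regulons, gene_dyn, tf_dyn, tf_state, lib)
    if return_rates:
        return cm, truth, mu
    return cm, truth


def _sample_nb(rng, mu, theta):
    if np.isinf(theta):
        return rng.poisson(mu)
    lam = rng.gamma(theta, mu / theta)
    return rng.poisson(lam)


def _apply_artifact(rng, counts, c, kind, blocks, gidx, mu, config):
    if kind == "low-gene":
        # redraw the cell at a tiny library (< 200 detected genes)
        small = rng.uniform(80, 150)
        col = mu[:, c] / mu[:, c].sum() * small
        counts[:, c] = rng.poisson(col)
    elif kind == "high-mito":
        frac = rng.uniform(0.10, 0.25)
        _boost_block(rng, counts, c, [gidx[g] for g in blocks["mito"]], frac)
    elif kind == "high-dissoc":
        frac = rng.uniform(0.06, 0.15)
        _boost_block(rng, counts, c, [gidx[g] for g in blocks["dissociation"]], frac)
    elif kind == "t-contaminant":
        for g in blocks["tcell"]:
            counts[gidx[g], c] += rng.poisson(8) + 1


def _boost_block(rng, counts, c, rows, target_frac):
    total = counts[:, c].sum()
    current = counts[rows, c].sum()
    # add counts so the block reaches target_frac of the new total
    add = int(np.ceil((target_frac * total - current) / (1 - target_frac)))
    if add > 0:
        alloc = rng.multinomial(add, np.ones(len(rows)) / len(rows))
        counts[rows, c] += alloc


def write_truth(truth: SimTruth, path) -> None:
    """Ground truth as a cell TSV plus GMT of the true regulons."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    truth.cells.to_csv(path / "cells.tsv", sep="\t")
    write_gmt({tf: set(t) for tf, t in truth.regulons_true.regulons.items()},
              path / "regulons_true.gmt", description="planted")
    dyn = pd.DataFrame(
        {"feature": list(truth.gene_dynamics) + list(truth.tf_dynamics),
         "kind": ["gene"] * len(truth.gene_dynamics) + ["tf"] * len(truth.tf_dynamics),
         "dynamic": list(truth.gene_dynamics.values()) + list(truth.tf_dynamics.values())}
    )
    dyn.to_csv(path / "dynamics.tsv", sep="\t", index=False)


def write_simulation(config: SimConfig, out_dir, overwrite: bool = False):
    """Run the generator and write counts (10x layout), truth and config."""
    out_dir = Path(out_dir)
    cm, truth = simulate_counts(config)
    write_tenx_directory(cm, out_dir / "counts", overwrite=overwrite)
    write_truth(truth, out_dir / "truth")
    config.to_yaml(out_dir / "sim_config.yaml")
    return cm, truth
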