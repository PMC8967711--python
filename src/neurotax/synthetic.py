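"""Synthetic two-species inhibitory-neuron datasets with known ground truth.

The generator emulates the structure the analysis pipeline assumes in real
developmental data:

* branching differentiation: each class is a branch along which cells sit at
  a uniform true latent time in [0, 1];
* two-state transcription kinetics: every dynamic gene follows the standard
  spliced/unspliced ODE (du/dt = alpha(t) - beta*u, ds/dt = beta*u - gamma*s)
  with a per-gene on-window [t_on, t_off), so unspliced counts lead spliced
  counts along the branch;
* a shared early cell-cycle/progenitor programme that switches off as cells
  differentiate;
* class-specific transcription-factor marker programmes, including
  GAD/DLX-analogue interneuron markers that are silent in a planted
  excitatory outgroup branch;
* a cross-species design in which most classes are shared between the two
  species and one class exists in a single species but shares its programme
  with a designated "sister" class (plus a disjoint private marker set);
* batch effects, library-size variation, negative-binomial overdispersion,
  and planted low-quality cells that violate the droplet QC thresholds.

All distributional choices are stand-ins: the real study provides no
generative model, so the simulator is designed to be structurally faithful
(kinetics, branching, batch design) rather than calibrated to any tissue.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import anndata as ad
import numpy as np
import pandas as pd

from ._utils import ConfigurationError, as_dense, logger

INHIBITORY_MARKERS = ("GAD1", "GAD2", "DLX1", "DLX2", "DLX5", "DLX6")


@dataclass(frozen=True)
class KineticParams:
    """Sampling ranges for per-gene two-state transcription kinetics.

    Rates are in reciprocal latent-time units (latent time spans [0, 1]):
    ``alpha`` is the on-state transcription rate, ``beta`` the splicing rate
    and ``gamma`` the degradation rate.  Per-gene values are drawn uniformly
    within ``rel_jitter`` of the central value, so the steady-state ratio
    gamma/beta varies across genes.  ``t_on < t_off`` bound the on-window of
    marker programmes; with beta, gamma well above 1/(t_off - t_on) the
    spliced abundance reaches its plateau alpha/gamma within the window,
    which is what the steady-state velocity estimator assumes.
    """

    alpha: float = 14.0
    beta: float = 8.0
    gamma: float = 3.6
    t_on: float = 0.0
    t_off: float = 1.5
    rel_jitter: float = 0.25

    def validate(self) -> None:
        for name in ("alpha", "beta", "gamma"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"kinetic rate {name} must be strictly positive")
        if not self.t_on < self.t_off:
            raise ConfigurationError("kinetics require t_on < t_off")
        if not 0 <= self.rel_jitter < 1:
            raise ConfigurationError("rel_jitter must lie in [0, 1)")


@dataclass(frozen=True)
class TrajectoryDesign:
    """Layout of the simulated two-species branching experiment."""

    species: tuple[str, ...] = ("macaque", "mouse")
    shared_classes: tuple[str, ...] = (
        "MGE_CRABP1_MAF",
        "LGE_MEIS2_PAX6",
        "CGE_NR2F2_PROX1",
        "VMF_ZIC1_ZIC2",
    )
    specific_class: str = "MGE_CRABP1_TAC3"
    specific_species: str = "macaque"
    sister_class: str = "MGE_CRABP1_MAF"
    cross_species: bool = True
    include_excitatory: bool = True
    excitatory_class: str = "EXC_NEUROD2"
    cells_per_branch: int = 450
    batches_per_species: int = 2
    n_genes: int = 2100
    n_markers_per_class: int = 40
    n_tf_per_class: int = 25
    n_specific_markers: int = 30
    n_specific_tf: int = 25
    n_cycling_genes: int = 40
    n_maturation_genes: int = 40
    n_noise_genes: int = 600
    fraction_low_quality: float = 0.08
    orthologue_dropout: float = 0.05
    terminal_time: float = 0.8
    seed: int = 0

    def validate(self) -> None:
        if len(self.species) != 2:
            raise ConfigurationError("design requires exactly two species")
        if self.cells_per_branch < 2:
            raise ConfigurationError("every branch needs at least 2 cells")
        if self.cross_species:
            if not self.shared_classes:
                raise ConfigurationError(
                    "cross-species mode requires at least one shared class"
                )
            if not self.specific_class:
                raise ConfigurationError(
                    "cross-species mode requires a species-specific class"
                )
            if self.specific_species not in self.species:
                raise ConfigurationError("specific_species must be one of the species")
            if self.sister_class not in self.shared_classes:
                raise ConfigurationError("sister_class must be a shared class")
        if not 0 <= self.fraction_low_quality <= 0.5:
            raise ConfigurationError("fraction_low_quality must lie in [0, 0.5]")
        if not 0 < self.terminal_time < 1:
            raise ConfigurationError("terminal_time must lie in (0, 1)")
        n_special = (
            (self.n_markers_per_class + self.n_tf_per_class)
            * (len(self.shared_classes) + 1)
            + self.n_specific_markers
            + self.n_specific_tf
            + self.n_cycling_genes
            + self.n_maturation_genes
            + self.n_noise_genes
            + len(INHIBITORY_MARKERS)
            + 105  # mito + ribo blocks
        )
        if self.n_genes < n_special + 100:
            raise ConfigurationError(
                f"n_genes={self.n_genes} too small for the configured programmes "
                f"(need at least {n_special + 100})"
            )

    def branches(self, species: str) -> list[str]:
        out = list(self.shared_classes)
        if self.cross_species and species == self.specific_species:
            out.append(self.specific_class)
        if self.include_excitatory:
            out.append(self.excitatory_class)
        return out


@dataclass
class SyntheticTruth:
    """Ground truth for a generated dataset.

    ``cells`` maps species -> per-cell frame with true latent time, class,
    terminal class and quality flag.  ``expected`` maps species -> noiseless
    expected spliced/unspliced matrices (before library-size scaling and
    sampling), which parameter-recovery tests compare against.
    """

    cells: dict[str, pd.DataFrame]
    genes: pd.DataFrame
    programs: pd.DataFrame
    homology: dict[str, str]
    specific_class: str
    sister_class: str
    orthologues: pd.DataFrame
    expected: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)

    def validate(self) -> None:
        for sp_name, frame in self.cells.items():
            t = frame["latent_time"].to_numpy()
            if t.min() < 0 or t.max() > 1:
                raise ConfigurationError(f"latent time outside [0,1] for {sp_name}")
        values = list(self.homology.values())
        if len(set(values)) != len(values):
            raise ConfigurationError("homology map must be a bijection on shared classes")


def two_state_expected(t, alpha, beta, gamma, t_on, t_off, base=0.0):
    """Expected (unspliced, spliced) abundance under the two-state ODE.

    ``t`` is a column of cell times; the rate parameters broadcast as gene
    rows.  Before ``t_on`` the gene rests at the primed baseline ``base``
    (its own steady state); during [t_on, t_off) transcription runs at
    ``base*gamma + alpha``; afterwards it relaxes back to the baseline.
    """
    t = np.asarray(t, dtype=float)[:, None]
    alpha, beta, gamma, t_on, t_off, base = np.broadcast_arrays(
        *(np.atleast_1d(np.asarray(x, dtype=float)) for x in (alpha, beta, gamma, t_on, t_off, base))
    )
    # avoid the beta == gamma removable singularity
    gamma = np.where(np.abs(gamma - beta) < 1e-6, gamma + 1e-5, gamma)

    u0 = base * gamma / beta
    s0 = base

    def _relax(tau, u_start, s_start, u_inf, s_inf):
        A = u_start - u_inf
        C = beta * A / (gamma - beta)
        B = s_start - s_inf - C
        u = u_inf + A * np.exp(-beta * tau)
        s = s_inf + B * np.exp(-gamma * tau) + C * np.exp(-beta * tau)
        return u, s

    # induction phase targets
    u_on = (base * gamma + alpha) / beta
    s_on = (base * gamma + alpha) / gamma

    tau_on = np.clip(t - t_on, 0.0, None)
    u_ind, s_ind = _relax(tau_on, u0, s0, u_on, s_on)

    # state at switch-off, then relaxation back to baseline
    tau_off_len = np.clip(t_off - t_on, 0.0, None)
    u1, s1 = _relax(tau_off_len, u0, s0, u_on, s_on)
    tau_off = np.clip(t - t_off, 0.0, None)
    A2 = u1 - u0
    C2 = beta * A2 / (gamma - beta)
    B2 = s1 - s0 - C2
    u_rep = u0 + A2 * np.exp(-beta * tau_off)
    s_rep = s0 + B2 * np.exp(-gamma * tau_off) + C2 * np.exp(-beta * tau_off)

    pre = t < t_on
    post = t >= t_off
    u = np.where(pre, u0, np.where(post, u_rep, u_ind))
    s = np.where(pre, s0, np.where(post, s_rep, s_ind))
    return u, s


def _build_gene_table(design: TrajectoryDesign, kinetics: KineticParams, rng) -> pd.DataFrame:
    """Assign every gene a group, per-species names and kinetic parameters."""
    marker_classes = list(design.shared_classes)
    if design.include_excitatory:
        marker_classes.append(design.excitatory_class)

    rows = []
    for cls in marker_classes:
        for i in range(design.n_markers_per_class):
            rows.append({"gene": f"{cls}.M{i:02d}", "group": f"marker:{cls}"})
        # regional transcription factors: constant-high in their branch from
        # t = 0, since an initial class is defined by TFs present at or
        # before the final division
        for i in range(design.n_tf_per_class):
            rows.append({"gene": f"{cls}.TF{i:02d}", "group": f"tf:{cls}"})
    for i in range(design.n_specific_markers):
        rows.append({"gene": f"{design.specific_class}.S{i:02d}", "group": "specific_marker"})
    for i in range(design.n_specific_tf):
        rows.append({"gene": f"{design.specific_class}.TF{i:02d}", "group": "specific_tf"})
    for i in range(design.n_cycling_genes):
        name = ["MKI67", "TOP2A", "CCNB1", "CDK1", "AURKA"][i] if i < 5 else f"CYC.{i:02d}"
        rows.append({"gene": name, "group": "cycling"})
    for i in range(design.n_maturation_genes):
        name = ["SYT1", "SNAP25", "MAP2", "RBFOX3", "SYN1"][i] if i < 5 else f"MAT.{i:02d}"
        rows.append({"gene": name, "group": "maturation"})
    for name in INHIBITORY_MARKERS:
        rows.append({"gene": name, "group": "inhibitory"})
    for i in range(25):
        rows.append({"gene": f"MT-G{i:02d}", "group": "mito"})
    for i in range(80):
        prefix = "RPS" if i < 40 else "RPL"
        rows.append({"gene": f"{prefix}{i:02d}", "group": "ribo"})
    for i in range(design.n_noise_genes):
        rows.append({"gene": f"NS.{i:04d}", "group": "noise"})
    n_hk = design.n_genes - len(rows)
    for i in range(n_hk):
        rows.append({"gene": f"HK.{i:04d}", "group": "housekeeping"})

    genes = pd.DataFrame(rows).set_index("gene")
    n = len(genes)
    j = kinetics.rel_jitter
    genes["alpha"] = kinetics.alpha * rng.uniform(1 - j, 1 + j, n)
    genes["beta"] = kinetics.beta * rng.uniform(1 - j, 1 + j, n)
    genes["gamma"] = kinetics.gamma * rng.uniform(1 - j, 1 + j, n)
    genes["t_on"] = kinetics.t_on
    genes["t_off"] = kinetics.t_off
    # effector markers activate in staggered waves along differentiation, so
    # expression keeps changing over the whole trajectory rather than
    # plateauing early (and latent time stays identifiable throughout)
    mk = genes.group.str.startswith(("marker:", "specific_marker")).to_numpy()
    genes.loc[mk, "t_on"] = rng.uniform(0.0, 0.6, int(mk.sum()))
    # pan-neuronal maturation programme: shared by all branches, activating
    # in staggered waves across the whole trajectory -- the substrate of a
    # *shared* latent time across classes
    mat = (genes.group == "maturation").to_numpy()
    genes.loc[mat, "t_on"] = rng.uniform(0.0, 0.8, int(mat.sum()))
    # progenitor/cycling programme: already on before the branch starts
    # (t_on < 0), switching off shortly after the final division, so its
    # expression is maximal in the youngest cells and decays monotonically.
    # Amplitude is kept at roughly half the marker plateau: these are
    # postmitotic cells carrying residual cycle transcripts, not cycling
    # progenitors, and class identity (TFs) dominates from birth.
    cyc = (genes.group == "cycling").to_numpy()
    genes.loc[cyc, "t_on"] = -1.0
    genes.loc[cyc, "t_off"] = 0.12
    genes.loc[cyc, "alpha"] = genes.loc[cyc, "alpha"] * 0.5
    genes["theta"] = rng.uniform(8.0, 15.0, n)  # NB dispersion (size parameter)

    # constant expression levels for non-dynamic genes
    level = np.zeros(n)
    hk = (genes.group == "housekeeping").to_numpy()
    level[hk] = np.exp(rng.normal(0.45, 0.30, hk.sum()))
    # lowly expressed background genes: in real data the low-mean dispersion
    # bins are dominated by genes like these, so variable genes stand out
    ns = (genes.group == "noise").to_numpy()
    level[ns] = np.exp(rng.normal(-1.3, 0.8, ns.sum()))
    level[(genes.group == "mito").to_numpy()] = 2.2
    level[(genes.group == "ribo").to_numpy()] = 1.9
    level[(genes.group == "inhibitory").to_numpy()] = 2.5
    genes["const_level"] = level
    genes["is_mito"] = (genes.group == "mito").to_numpy()
    genes["is_ribo"] = (genes.group == "ribo").to_numpy()

    # species-level gene names; the "mouse-style" second species uses
    # capitalised symbols, and the private markers of the species-specific
    # class are absent from the second species' genome annotation
    sp_a, sp_b = design.species
    genes[f"name_{sp_a}"] = genes.index
    genes[f"name_{sp_b}"] = [g.capitalize() for g in genes.index]
    genes["in_both"] = ~(genes.group == "specific_marker").to_numpy()
    genes["tf_level"] = np.where(
        genes.group.str.startswith(("tf:", "specific_tf")),
        3.5 * rng.uniform(0.8, 1.2, len(genes)),
        0.0,
    )
    return genes


def _active_window_genes(genes: pd.DataFrame, design: TrajectoryDesign, branch: str):
    """Boolean mask over genes for the dynamic programme of one branch."""
    group = genes["group"]
    active = group == f"marker:{branch}"
    if branch == design.specific_class:
        # sister programme plus the private marker set
        active = (group == f"marker:{design.sister_class}") | (group == "specific_marker")
    active = active | (group == "cycling") | (group == "maturation")
    return active.to_numpy()


def generate_dataset(
    design: TrajectoryDesign, kinetics: KineticParams | None = None
) -> tuple[dict[str, ad.AnnData], SyntheticTruth]:
    """Simulate per-species ExpressionDatasets plus their ground truth.

    Deterministic for a fixed (design, kinetics): all draws flow from
    ``design.seed`` through one generator in a fixed order.
    """
    design.validate()
    kinetics = kinetics or KineticParams()
    kinetics.validate()
    rng = np.random.default_rng(design.seed)

    genes = _build_gene_table(design, kinetics, rng)
    sp_a, sp_b = design.species
    # mild species/batch multiplicative effects on expected counts
    species_factor = {
        s: np.exp(rng.normal(0.0, 0.10, len(genes))) for s in design.species
    }

    marker_base = 1.0  # primed baseline of a class's markers within its branch
    datasets: dict[str, ad.AnnData] = {}
    truth_cells: dict[str, pd.DataFrame] = {}
    expected: dict[str, dict[str, np.ndarray]] = {}

    for species in design.species:
        branches = design.branches(species)
        keep_genes = genes if species == sp_a else genes[genes["in_both"]]
        gidx = genes.index.get_indexer(keep_genes.index)
        n_genes_sp = len(keep_genes)

        batch_labels = [f"{species}_b{k}" for k in range(design.batches_per_species)]
        batch_factor = {
            b: np.exp(rng.normal(0.0, 0.08, len(genes))) for b in batch_labels
        }

        per_branch_u, per_branch_s, cell_rows = [], [], []
        for branch in branches:
            n = design.cells_per_branch
            t = rng.uniform(0.0, 1.0, n)
            active = _active_window_genes(genes, design, branch)

            U = np.zeros((n, len(genes)))
            S = np.zeros((n, len(genes)))
            g = genes.loc[active]
            base = np.where(g["group"].str.startswith(("marker", "specific")), marker_base, 0.0)
            u_act, s_act = two_state_expected(
                t,
                g["alpha"].to_numpy(),
                g["beta"].to_numpy(),
                g["gamma"].to_numpy(),
                g["t_on"].to_numpy(),
                g["t_off"].to_numpy(),
                base,
            )
            U[:, active] = u_act
            S[:, active] = s_act

            const = genes["const_level"].to_numpy().copy()
            if branch == design.excitatory_class:
                const[(genes["group"] == "inhibitory").to_numpy()] = 0.0
            # branch-defining TFs: constant-high from t=0 in their own branch
            tf_on = (genes["group"] == f"tf:{branch}").to_numpy()
            const[tf_on] = genes["tf_level"].to_numpy()[tf_on]
            if branch == design.specific_class:
                # the sister pair shares a regional TF code (first half of the
                # sister's TFs) while each member keeps a private subtype code
                sis = np.where((genes["group"] == f"tf:{design.sister_class}").to_numpy())[0]
                shared_code = sis[: len(sis) // 2 + len(sis) % 2]
                const[shared_code] = genes["tf_level"].to_numpy()[shared_code]
                own = (genes["group"] == "specific_tf").to_numpy()
                const[own] = genes["tf_level"].to_numpy()[own]
            S += const[None, :]
            U += (const * genes["gamma"].to_numpy() / genes["beta"].to_numpy())[None, :]

            region = branch.split("_")[0] if branch.split("_")[0] in ("MGE", "LGE", "CGE", "VMF") else "CTX"
            for i in range(n):
                cell_rows.append(
                    {
                        "species": species,
                        "batch": batch_labels[int(rng.integers(len(batch_labels)))],
                        "region": region,
                        "latent_time": t[i],
                        "class": branch,
                        "terminal_class": f"T_{branch}",
                        "is_terminal": bool(t[i] >= design.terminal_time),
                    }
                )
            per_branch_u.append(U)
            per_branch_s.append(S)

        U_all = np.vstack(per_branch_u)[:, gidx]
        S_all = np.vstack(per_branch_s)[:, gidx]
        cells = pd.DataFrame(cell_rows)
        cells.index = pd.Index(
            [f"{species}_{i:05d}" for i in range(len(cells))], name="barcode"
        )

        lib = np.clip(np.exp(rng.normal(0.0, 0.18, len(cells))), 0.75, 1.5)
        bfac = np.stack([batch_factor[b][gidx] for b in cells["batch"]])
        sfac = species_factor[species][gidx]
        mu_s = S_all * lib[:, None] * bfac * sfac[None, :]
        mu_u = U_all * (0.45 * lib)[:, None] * bfac * sfac[None, :]

        theta = keep_genes["theta"].to_numpy()
        spliced = _nb_sample(rng, mu_s, theta)
        unspliced = _nb_sample(rng, mu_u, theta)

        var = keep_genes[["group", "is_mito", "is_ribo", "alpha", "beta", "gamma", "t_on", "t_off"]].copy()
        var.index = pd.Index(keep_genes[f"name_{species}"], name="gene")
        obs = cells[["species", "batch", "region", "terminal_class", "is_terminal"]].copy()
        obs["age"] = np.where(cells["latent_time"] < 0.5, "early", "late")

        adata = ad.AnnData(X=spliced.copy(), obs=obs, var=var)
        adata.layers["spliced"] = spliced
        adata.layers["unspliced"] = unspliced

        adata, flags = plant_qc_artifacts(
            adata, design.fraction_low_quality, seed=int(rng.integers(2**31))
        )
        _repair_good_cells(adata, rng)
        cells["quality"] = np.where(flags["flagged"].to_numpy(), "low_quality", "good")
        cells["qc_reason"] = flags["reason"].to_numpy()

        datasets[species] = adata
        truth_cells[species] = cells
        expected[species] = {
            "spliced": S_all.astype(np.float32),
            "unspliced": U_all.astype(np.float32),
        }

    # orthologue table over genes present in both species, with dropout
    both = genes[genes["in_both"]]
    keep = rng.random(len(both)) >= design.orthologue_dropout
    orth = pd.DataFrame(
        {"geneA": both[f"name_{sp_a}"].to_numpy(), "geneB": both[f"name_{sp_b}"].to_numpy()}
    )[keep].reset_index(drop=True)

    programs = _program_table(genes, design)
    homology = {c: c for c in design.shared_classes} if design.cross_species else {}
    truth = SyntheticTruth(
        cells=truth_cells,
        genes=genes,
        programs=programs,
        homology=homology,
        specific_class=design.specific_class if design.cross_species else "",
        sister_class=design.sister_class if design.cross_species else "",
        orthologues=orth,
        expected=expected,
    )
    truth.validate()
    return datasets, truth


def _nb_sample(rng, mu: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Negative-binomial counts with gene-wise size parameter theta."""
    p = theta[None, :] / (theta[None, :] + mu)
    return rng.negative_binomial(theta[None, :], np.clip(p, 1e-12, 1.0)).astype(np.int32)


def _program_table(genes: pd.DataFrame, design: TrajectoryDesign) -> pd.DataFrame:
    """Per (class, gene) trajectory role: activated, inactivated or null."""
    rows = []
    for species in design.species:
        for branch in design.branches(species):
            active = _active_window_genes(genes, design, branch)
            for gene, is_active, group in zip(genes.index, active, genes["group"]):
                if not is_active:
                    continue
                role = "inactivated" if group == "cycling" else "activated"
                rows.append({"class": branch, "gene": gene, "role": role})
    return pd.DataFrame(rows).drop_duplicates()


def plant_qc_artifacts(
    dataset: ad.AnnData, fraction_low_quality: float, seed: int
) -> tuple[ad.AnnData, pd.DataFrame]:
    """Corrupt an exact fraction of cells so each fails >=1 droplet QC threshold.

    Three failure modes cycle over the flagged cells: fewer than 800 detected
    genes (counts outside a small retained gene set are zeroed), inflated
    mitochondrial fraction (> 15%), and inflated ribosomal fraction (> 40%).
    Returns the modified dataset and a per-cell flag table; flags are also
    stored in ``obs['qc_truth']`` / ``obs['qc_reason']``.
    """
    if not 0 <= fraction_low_quality <= 0.5:
        raise ConfigurationError("fraction_low_quality must lie in [0, 0.5]")
    rng = np.random.default_rng(seed)
    adata = dataset.copy()
    n = adata.n_obs
    n_flag = int(round(fraction_low_quality * n))
    flagged_idx = rng.choice(n, size=n_flag, replace=False) if n_flag else np.array([], dtype=int)

    X = as_dense(adata.layers["spliced"]).astype(np.int64)
    is_mito = adata.var["is_mito"].to_numpy().astype(bool)
    is_ribo = adata.var["is_ribo"].to_numpy().astype(bool)
    reasons = np.array([""] * n, dtype=object)
    modes = ["low_genes", "high_mito", "high_ribo"]
    for j, ci in enumerate(sorted(flagged_idx)):
        mode = modes[j % 3]
        row = X[ci]
        if mode == "low_genes":
            keep = rng.choice(adata.n_vars, size=min(500, adata.n_vars // 2), replace=False)
            mask = np.ones(adata.n_vars, dtype=bool)
            mask[keep] = False
            row[mask] = 0
        elif mode == "high_mito":
            other = row[~is_mito].sum()
            target = int(np.ceil(0.35 / (1 - 0.35) * other))
            row[is_mito] = _spread_counts(rng, target, is_mito.sum())
        else:
            other = row[~is_ribo].sum()
            target = int(np.ceil(0.55 / (1 - 0.55) * other))
            row[is_ribo] = _spread_counts(rng, target, is_ribo.sum())
        X[ci] = row
        reasons[ci] = mode

    X = X.astype(np.int32)
    adata.layers["spliced"] = X
    adata.X = X.copy()
    flags = pd.DataFrame(
        {"flagged": reasons != "", "reason": reasons}, index=adata.obs_names
    )
    adata.obs["qc_truth"] = np.where(flags["flagged"], "low_quality", "good")
    adata.obs["qc_reason"] = flags["reason"].to_numpy()
    return adata, flags


def _spread_counts(rng, total: int, n_bins: int) -> np.ndarray:
    if total <= 0:
        return np.zeros(n_bins, dtype=np.int64)
    return rng.multinomial(total, np.full(n_bins, 1.0 / n_bins))


def _repair_good_cells(adata: ad.AnnData, rng) -> None:
    """Guarantee that unflagged cells pass the default droplet QC thresholds.

    Sampling noise can leave a nominally good cell marginally below the
    800-detected-genes floor; such cells get extra singleton counts spread
    over undetected genes.  Mito/ribo fractions are similarly capped.
    """
    X = as_dense(adata.layers["spliced"]).astype(np.int64)
    good = (adata.obs["qc_truth"] == "good").to_numpy()
    is_mito = adata.var["is_mito"].to_numpy().astype(bool)
    is_ribo = adata.var["is_ribo"].to_numpy().astype(bool)
    changed = 0
    for ci in np.where(good)[0]:
        row = X[ci]
        detected = int((row > 0).sum())
        if detected < 820:
            zeros = np.where(row == 0)[0]
            add = rng.choice(zeros, size=min(820 - detected, len(zeros)), replace=False)
            row[add] = 1
            changed += 1
        total = row.sum()
        for mask, cap in ((is_mito, 0.12), (is_ribo, 0.35)):
            frac = row[mask].sum() / max(total, 1)
            if frac > cap:
                row[mask] = (row[mask] * (cap * total / row[mask].sum() * 0.9)).astype(np.int64)
                changed += 1
        X[ci] = row
    if changed:
        logger.info("repaired %d good cells to QC margins", changed)
    X = X.astype(np.int32)
    adata.layers["spliced"] = X
    adata.X = X.copy()


def default_demo_design(seed: int = 0, cells_per_branch: int = 450) -> TrajectoryDesign:
    """The bundled demo configuration: 2 species, 4 shared classes + 1
    species-specific class + an excitatory outgroup, ~5,000 cells."""
    return replace(TrajectoryDesign(), seed=seed, cells_per_branch=cells_per_branch)
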