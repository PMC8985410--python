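"""Synthetic inputs for every stage of the driver-gene pipeline.

The generators here produce data with the statistical structure the
downstream stages assume: multi-group log2 expression with planted
coexpression modules and differentially expressed genes, five-channel
evidence tables for CFG scoring, a low-rank drug-target interaction
matrix with side features, and a small interactome carrying drug-target
and disease-gene modules.  The printed 40-row driver-gene evidence table
ships as a package fixture and is loaded by :func:`driver_gene_evidence`.

Planted modules use a latent-factor construction: each member gene is
``sqrt(rho) * factor + sqrt(1 - rho) * noise`` so that the pairwise
within-module correlation has the closed form ``rho`` and generator
properties are analytically checkable.  Differential expression is an
additive shift applied to case samples only, so the expected log fold
change equals the shift.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .cfg import AD_CORE_GENES, GeneEvidence


@dataclass
class SimulationConfig:
    """Parameters of the expression generator.

    ``within_module_correlation`` is the target pairwise Pearson r of
    genes sharing a planted module; ``deg_effect_size`` is the additive
    shift (log2 units) applied to AD samples of planted DEGs;
    ``noise_sd`` scales the independent per-gene noise.
    """

    n_genes: int = 600
    n_samples_per_group: int = 60
    module_sizes: tuple[int, ...] = (50, 50, 50)
    within_module_correlation: float = 0.7
    deg_fraction: float = 0.1
    deg_effect_size: float = 1.0
    deg_module_enrichment: float = 0.7
    noise_sd: float = 0.5
    baseline_mean: float = 7.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.n_samples_per_group <= 0:
            raise ValueError("n_genes and n_samples_per_group must be positive")
        if sum(self.module_sizes) > self.n_genes:
            raise ValueError(
                f"module sizes sum to {sum(self.module_sizes)} "
                f"but only {self.n_genes} genes requested"
            )
        if not 0.0 < self.within_module_correlation < 1.0:
            raise ValueError("within_module_correlation must lie in (0, 1)")
        if not 0.0 <= self.deg_fraction <= 1.0:
            raise ValueError("deg_fraction must lie in [0, 1]")
        if not 0.0 <= self.deg_module_enrichment <= 1.0:
            raise ValueError("deg_module_enrichment must lie in [0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")

    @property
    def n_modules(self) -> int:
        return len(self.module_sizes)


@dataclass
class ExpressionStudy:
    """A gene-by-sample log2 expression matrix with binary phenotype labels.

    ``phenotype`` is 0 for control and 1 for AD, aligned with
    ``sample_ids``.  ``truth`` (present only for simulated studies) records
    the planted module label per gene (0 = background) and the planted DEG
    flag per gene.
    """

    values: pd.DataFrame  # genes x samples
    phenotype: pd.Series  # sample -> {0, 1}
    dataset_name: str = "synthetic"
    truth: dict | None = None

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        if not self.values.index.is_unique:
            raise ValueError("duplicate gene ids")
        if not self.values.columns.is_unique:
            raise ValueError("duplicate sample ids")
        if set(self.phenotype.unique()) != {0, 1}:
            raise ValueError("phenotype must contain both classes (0 and 1)")
        if list(self.phenotype.index) != list(self.values.columns):
            raise ValueError("phenotype index must match sample columns")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class InteractomeFixture:
    """A toy undirected interactome with planted drug and disease modules."""

    graph: nx.Graph
    drug_modules: dict[str, set[str]]
    disease_module: set[str]

    def __post_init__(self) -> None:
        if any(self.graph.has_edge(n, n) for n in self.graph):
            raise ValueError("interactome must not contain self-loops")
        nodes = set(self.graph)
        for drug, module in self.drug_modules.items():
            if not module <= nodes:
                raise ValueError(f"drug module {drug} has members outside the graph")
        if not self.disease_module <= nodes:
            raise ValueError("disease module has members outside the graph")


@dataclass
class DrugTargetData:
    """Binary interaction matrix plus drug/target feature matrices.

    ``P`` has a 1 where a drug-target interaction is observed and 0 where
    the entry is unobserved (PU convention).  ``truth`` retains the latent
    factors and the noiseless score matrix used to plant ``P``.
    """

    P: np.ndarray
    X: np.ndarray
    Y: np.ndarray
    drug_ids: list[str] = field(default_factory=list)
    target_ids: list[str] = field(default_factory=list)
    truth: dict | None = None


def simulate_expression(config: SimulationConfig) -> ExpressionStudy:
    """Generate a two-group expression study with planted structure.

    Module members share a latent per-sample factor with loading
    ``sqrt(rho)``, giving expected within-module Pearson correlation
    ``rho``.  A ``deg_fraction`` of genes (spread over modules and
    background) receives an additive ``deg_effect_size`` shift in AD
    samples.  All remaining variation is independent Gaussian noise.
    """
    rng = np.random.default_rng(config.seed)
    n = 2 * config.n_samples_per_group
    g = config.n_genes
    phenotype = np.repeat([0, 1], config.n_samples_per_group)

    rho = config.within_module_correlation
    module_label = np.zeros(g, dtype=int)
    start = 0
    for m, size in enumerate(config.module_sizes, start=1):
        module_label[start : start + size] = m
        start += size

    factors = rng.standard_normal((config.n_modules, n))
    noise = rng.standard_normal((g, n))
    signal = np.zeros((g, n))
    for m in range(1, config.n_modules + 1):
        members = module_label == m
        signal[members] = np.sqrt(rho) * factors[m - 1]
        noise[members] *= np.sqrt(1.0 - rho)
    values = config.baseline_mean + config.noise_sd * (signal + noise)

    # DEGs are planted preferentially inside modules (disease-responsive
    # coexpression modules are the structure the downstream stages look for)
    n_degs = int(round(config.deg_fraction * g))
    in_module = np.flatnonzero(module_label > 0)
    background = np.flatnonzero(module_label == 0)
    n_in = min(int(round(config.deg_module_enrichment * n_degs)), in_module.size)
    n_out = min(n_degs - n_in, background.size)
    deg_idx = np.concatenate(
        [
            rng.choice(in_module, size=n_in, replace=False),
            rng.choice(background, size=n_out, replace=False),
        ]
    ).astype(int)
    is_deg = np.zeros(g, dtype=bool)
    is_deg[deg_idx] = True
    # shift applied to AD samples only, so E[logFC] equals the shift
    values[deg_idx] += config.deg_effect_size * phenotype[np.newaxis, :]

    gene_ids = [f"G{i:05d}" for i in range(g)]
    sample_ids = [f"S{i:04d}" for i in range(n)]
    frame = pd.DataFrame(values, index=gene_ids, columns=sample_ids)
    pheno = pd.Series(phenotype, index=sample_ids, name="phenotype")
    truth = {
        "module": pd.Series(module_label, index=gene_ids, name="module"),
        "is_deg": pd.Series(is_deg, index=gene_ids, name="is_deg"),
    }
    return ExpressionStudy(values=frame, phenotype=pheno, truth=truth)


def simulate_evidence(
    gene_ids: list[str],
    prevalence: dict[str, float] | float = 0.3,
    seed: int = 0,
) -> list[GeneEvidence]:
    """Draw a five-channel evidence table with given per-channel prevalence.

    ``prevalence`` is either a single probability applied to all channels
    or a mapping with keys ``gwas``, ``eqtl``, ``ppi``, ``pathology`` and
    ``early``.  Channels that are "absent" are encoded the way real
    evidence tables encode absence: a zero count, an empty partner set,
    an ``ns`` correlation, or an NA flag.
    """
    if not gene_ids:
        raise ValueError("gene_ids must be non-empty")
    channels = ("gwas", "eqtl", "ppi", "pathology", "early")
    if isinstance(prevalence, (int, float)):
        prev = {c: float(prevalence) for c in channels}
    else:
        prev = {c: float(prevalence.get(c, 0.0)) for c in channels}
    for c, p in prev.items():
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"prevalence for {c} must lie in [0, 1]")

    rng = np.random.default_rng(seed)
    core = sorted(AD_CORE_GENES)
    rows = []
    for gene in gene_ids:
        has = {c: rng.random() < prev[c] for c in channels}
        n_partners = rng.integers(1, len(core) + 1) if has["ppi"] else 0
        partners = frozenset(rng.choice(core, size=n_partners, replace=False))
        sig = str(rng.choice(["p05", "p01", "p001"]))
        r_abeta = float(np.round(rng.uniform(-0.9, 0.9), 3))
        r_tau = float(np.round(rng.uniform(-0.9, 0.9), 3))
        rows.append(
            GeneEvidence(
                gene=gene,
                eqtl_count=int(rng.integers(1, 17)) if has["eqtl"] else 0,
                gwas_locus_count=int(rng.integers(1, 42)) if has["gwas"] else 0,
                ppi_core_partners=partners,
                early_deg="yes" if has["early"] else str(rng.choice(["no", "NA"])),
                abeta_cor=(r_abeta, sig if has["pathology"] else "ns"),
                tau_cor=(r_tau, "ns"),
            )
        )
    return rows


def simulate_drug_target(
    n_drugs: int = 40,
    n_targets: int = 30,
    rank: int = 5,
    density: float = 0.15,
    n_features: int | None = None,
    seed: int = 0,
) -> DrugTargetData:
    """Plant a low-rank drug-target interaction matrix with side features.

    Latent factors ``U`` (drugs) and ``V`` (targets) of the given rank are
    sampled; the noiseless score matrix is ``U @ V.T`` and the top
    ``density`` fraction of its entries become the observed positives of
    ``P``.  Feature matrices ``X`` and ``Y`` embed the latent factors in a
    higher-dimensional space through a random linear map, so a rank-``rank``
    bilinear model on (X, Y) can realize the planted scores exactly.
    """
    if rank > min(n_drugs, n_targets):
        raise ValueError("rank must not exceed min(n_drugs, n_targets)")
    if not 0.0 < density <= 1.0:
        raise ValueError("density must lie in (0, 1]")
    if n_features is None:
        n_features = 2 * rank

    rng = np.random.default_rng(seed)
    U = rng.standard_normal((n_drugs, rank))
    V = rng.standard_normal((n_targets, rank))
    scores = U @ V.T

    n_pos = int(round(density * scores.size))
    flat_order = np.argsort(scores, axis=None)[::-1]
    P = np.zeros(scores.size)
    P[flat_order[:n_pos]] = 1.0
    P = P.reshape(scores.shape)

    # embed latent factors via random full-column-rank linear maps
    A = rng.standard_normal((rank, n_features))
    B = rng.standard_normal((rank, n_features))
    X = U @ A
    Y = V @ B

    return DrugTargetData(
        P=P,
        X=X,
        Y=Y,
        drug_ids=[f"drug{i:03d}" for i in range(n_drugs)],
        target_ids=[f"tgt{j:03d}" for j in range(n_targets)],
        truth={"U": U, "V": V, "scores": scores},
    )


def simulate_interactome(
    n_background: int = 60,
    disease_size: int = 8,
    n_drugs: int = 3,
    targets_per_drug: int = 3,
    drug_distance: int | tuple[int, ...] = (1, 2, 3),
    edge_prob: float = 0.08,
    seed: int = 0,
) -> InteractomeFixture:
    """Build a small connected interactome with planted modules.

    A random background graph carries a clique-ish disease module; each
    drug's target set is attached to the disease module by a path of
    ``drug_distance`` hops (one value per drug, or a single int for all),
    so the proximity of drug targets to the disease module is
    controllable per drug.
    """
    if isinstance(drug_distance, int):
        distances = [drug_distance] * n_drugs
    else:
        distances = [drug_distance[d % len(drug_distance)] for d in range(n_drugs)]
    rng = np.random.default_rng(seed)
    G: nx.Graph = nx.gnp_random_graph(n_background, edge_prob, seed=int(rng.integers(2**31)))
    G = nx.relabel_nodes(G, {i: f"BG{i:03d}" for i in range(n_background)})
    # ensure connectivity by chaining components
    comps = [sorted(c) for c in nx.connected_components(G)]
    for a, b in zip(comps, comps[1:]):
        G.add_edge(a[0], b[0])

    disease = [f"DIS{i:02d}" for i in range(disease_size)]
    for i, u in enumerate(disease):
        for v in disease[i + 1 :]:
            if rng.random() < 0.6:
                G.add_edge(u, v)
    anchor = sorted(G.nodes)[0]
    for u in disease:
        G.add_edge(u, anchor)

    drug_modules: dict[str, set[str]] = {}
    for d in range(n_drugs):
        drug = f"DRUG{d}"
        targets = set()
        for t in range(targets_per_drug):
            prev = str(rng.choice(disease))
            for hop in range(distances[d]):
                node = f"T{d}_{t}_{hop}"
                G.add_edge(prev, node)
                prev = node
            targets.add(prev)
        drug_modules[drug] = targets

    return InteractomeFixture(
        graph=G, drug_modules=drug_modules, disease_module=set(disease)
    )


def driver_gene_evidence() -> pd.DataFrame:
    """The packaged 40-row driver-gene evidence table, as printed.

    Columns follow the evidence-TSV schema plus ``cfg_printed``, the
    published CFG score for each row.  The table intentionally contains
    IGFBP7 twice, exactly as printed.
    """
    ref = importlib.resources.files("convergene") / "data" / "driver_gene_evidence.tsv"
    with importlib.resources.as_file(ref) as path:
        frame = pd.read_csv(
            path, sep="\t", dtype={"eqtl_count": str, "gwas_count": str}
        )
    return frame
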