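"""Synthetic two-group scenarios with known ground truth.

The generator emulates the statistical structure the fitting machinery
assumes: jointly Gaussian expression generated by a linear structural
system Y = nu + B Y + U per group.  A scenario bundles a ground-truth
model per group, a decoy-padded pathway graph whose geodesics recover the
true skeleton, a DEG list (shifted nodes plus the chain endpoints), an
optional superfamily map whose members are noisy indicators of a shared
composite, and an evidence set covering any planted hidden edge — so every
pipeline stage can be exercised, and recovery measured, without any
external download.

Default effect sizes are one residual-SD mean shifts (delta_mu = 1) and a
path-coefficient difference of delta_beta = 0.5 at n = 150 samples per
group — comfortably detectable, so recovery studies measure method
correctness rather than raw power.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .graph import PathwayGraph
from .model import PathModel, check_block_recursive, check_bow_free
from .multigroup import GroupedData
from .refine import EvidenceSet
from .sem import SEMParameters, implied_covariance

__all__ = ["ScenarioConfig", "SyntheticScenario", "simulate_sem", "make_scenario"]


def simulate_sem(
    params: SEMParameters,
    n: int,
    seed: int | np.random.Generator = 0,
    variables: list | None = None,
) -> pd.DataFrame:
    """Draw n Gaussian samples from Y = (I - B)^-1 (nu + U), U ~ N(0, Psi)."""
    B = np.asarray(params.beta, float)
    Psi = np.asarray(params.psi, float)
    p = B.shape[0]
    IB = np.eye(p) - B
    if abs(np.linalg.det(IB)) < 1e-12:
        raise ValueError("invalid parameters: I - B is singular")
    evals = np.linalg.eigvalsh((Psi + Psi.T) / 2.0)
    if evals.min() <= 0:
        raise ValueError("invalid parameters: Psi is not positive definite")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    L = np.linalg.cholesky((Psi + Psi.T) / 2.0)
    U = rng.standard_normal((n, p)) @ L.T
    nu = np.zeros(p) if params.means is None else np.asarray(params.means, float)
    A = np.linalg.solve(IB, np.eye(p))
    Y = (nu + U) @ A.T
    cols = variables if variables is not None else [f"y{i + 1}" for i in range(p)]
    return pd.DataFrame(Y, columns=cols)


@dataclass(frozen=True)
class ScenarioConfig:
    """Sizes and effect sizes of a synthetic two-group study.

    ``n_genes`` genes form a causal chain; ``n_families`` superfamilies of
    ``family_size`` adjacent connector genes are emitted as noisy indicators
    of a latent composite.  ``delta_mu`` shifts the conditional mean of the
    shifted nodes in group 1 (units of residual SD); ``delta_beta`` is added
    to one path coefficient in group 1; ``hidden_edge_beta``, when nonzero,
    plants an edge present in the data-generating model of both groups but
    absent from the pathway (recoverable only through refinement).
    """

    n_genes: int = 12
    n_decoys: int = 4
    n_families: int = 2
    family_size: int = 2
    delta_mu: float = 1.0
    delta_beta: float = 0.5
    hidden_edge_beta: float = 0.0
    n_per_group: int = 150
    baseline_mean: float = 8.0
    member_noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.n_genes < 6:
            raise ValueError("need at least 6 genes for the default layout")
        if self.n_families * self.family_size > max(0, self.n_genes - 6):
            raise ValueError("too many family members for the chain length")
        if self.n_per_group < 3:
            raise ValueError("need at least 3 samples per group")


def _gene_names(k: int) -> list:
    return [f"G{i + 1:02d}" for i in range(k)]


@dataclass
class SyntheticScenario:
    """Ground truth plus every input file the pipeline consumes."""

    config: ScenarioConfig
    variables: list  # model-level variables (genes and family composites)
    genes: list  # observed gene identifiers (excludes decoys)
    pathway: PathwayGraph
    deg_list: list
    superfamily_map: dict
    evidence: EvidenceSet
    truth_group1: SEMParameters
    truth_group2: SEMParameters
    model: PathModel  # the true model skeleton over `variables`
    family_members: dict = field(default_factory=dict)
    shifted_nodes: list = field(default_factory=list)
    delta_beta_edge: tuple | None = None
    hidden_edge: tuple | None = None

    # -- data generation ----------------------------------------------
    def simulate(self, seed: int | None = None) -> GroupedData:
        """Gene-level expression for both groups (plus decoy noise genes)."""
        seed = self.config.seed if seed is None else seed
        rng = np.random.default_rng(seed)
        frames = []
        for truth in (self.truth_group1, self.truth_group2):
            V = simulate_sem(truth, self.config.n_per_group, rng, variables=self.variables)
            obs = {}
            for v in self.variables:
                if v in self.family_members:
                    sd = V[v].std(ddof=1)
                    for m in self.family_members[v]:
                        obs[m] = V[v] + self.config.member_noise_sd * sd * rng.standard_normal(len(V))
                else:
                    obs[v] = V[v]
            df = pd.DataFrame(obs)[self.genes]
            for d in sorted(self.pathway.nodes - set(self.genes)):
                df[d] = self.config.baseline_mean + rng.standard_normal(len(df))
            frames.append(df)
        return GroupedData(group1=frames[0], group2=frames[1])

    def variable_level_data(self, seed: int | None = None) -> GroupedData:
        """Model-variable-level data (composites observed directly)."""
        seed = self.config.seed if seed is None else seed
        rng = np.random.default_rng(seed)
        g1 = simulate_sem(self.truth_group1, self.config.n_per_group, rng, self.variables)
        g2 = simulate_sem(self.truth_group2, self.config.n_per_group, rng, self.variables)
        return GroupedData(group1=g1, group2=g2)

    # -- persistence ---------------------------------------------------
    def write(self, outdir, seed: int | None = None) -> dict:
        """Write all pipeline input files as plain TSV/text; returns the paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        gd = self.simulate(seed=seed)
        expr = pd.concat([gd.group1, gd.group2], axis=0, ignore_index=True)
        samples = [f"S{i + 1:03d}" for i in range(len(expr))]
        expr.index = samples
        labels = pd.Series(
            ["experimental"] * gd.n1 + ["control"] * gd.n2, index=samples, name="group"
        )
        paths = {
            "expression": outdir / "expression.tsv",
            "groups": outdir / "groups.tsv",
            "pathway": outdir / "pathway.tsv",
            "degs": outdir / "degs.txt",
            "superfamily": outdir / "superfamily.tsv",
            "evidence": outdir / "evidence.tsv",
            "truth": outdir / "truth.json",
        }
        expr.T.to_csv(paths["expression"], sep="\t")  # genes x samples on disk
        labels.to_frame().to_csv(paths["groups"], sep="\t")
        from .graph import write_pathway_table

        write_pathway_table(self.pathway, paths["pathway"])
        paths["degs"].write_text("\n".join(self.deg_list) + "\n")
        with open(paths["superfamily"], "w") as fh:
            for gene, fam in sorted(self.superfamily_map.items()):
                fh.write(f"{gene}\t{fam}\n")
        with open(paths["evidence"], "w") as fh:
            for pair in sorted(map(sorted, self.evidence.string_edges)):
                fh.write(f"{pair[0]}\t{pair[1]}\n")
        truth = {
            "variables": self.variables,
            "beta_group1": self.truth_group1.beta.tolist(),
            "beta_group2": self.truth_group2.beta.tolist(),
            "psi": self.truth_group1.psi.tolist(),
            "means_group1": self.truth_group1.means.tolist(),
            "means_group2": self.truth_group2.means.tolist(),
            "shifted_nodes": self.shifted_nodes,
            "delta_beta_edge": list(self.delta_beta_edge or ()),
            "hidden_edge": list(self.hidden_edge or ()),
        }
        paths["truth"].write_text(json.dumps(truth, indent=1))
        return paths


def make_scenario(config: ScenarioConfig | None = None, **overrides) -> SyntheticScenario:
    """Build the default two-group chain scenario from a config.

    The ground-truth skeleton is a causal chain over the model variables
    with alternating activation (+0.6) and inhibition (-0.5) links, unit
    error variances and baseline means near ``baseline_mean``.  Group 1
    receives the planted mean shifts and the path-coefficient difference.
    The emitted pathway is the gene-level chain plus decoy nodes hanging
    off it; geodesics between the DEGs therefore recover exactly the chain.
    """
    if config is None:
        config = ScenarioConfig(**overrides)
    elif overrides:
        raise ValueError("pass either a config or keyword overrides, not both")
    genes = _gene_names(config.n_genes)

    # Allocate family members among interior (connector) genes: the chain
    # endpoints and the DEG positions stay individual genes.
    interior = genes[1 : config.n_genes - 1]
    quarters = [genes[0], genes[config.n_genes // 3], genes[(2 * config.n_genes) // 3], genes[-1]]
    eligible = [g for g in interior if g not in quarters]
    family_members: dict[str, list] = {}
    superfamily_map: dict[str, str] = {}
    used: set = set()
    for f in range(config.n_families):
        fid = f"FAM{f + 1}"
        # take the first run of `family_size` adjacent eligible genes
        run = []
        for g in eligible:
            if g in used:
                continue
            if run and genes.index(g) != genes.index(run[-1]) + 1:
                run = []
            run.append(g)
            if len(run) == config.family_size:
                break
        if len(run) < config.family_size:
            raise ValueError("infeasible config: not enough adjacent connector genes")
        family_members[fid] = run
        used.update(run)
        for g in run:
            superfamily_map[g] = fid

    # Model-level variables: collapse each family run onto its composite.
    variables: list = []
    gene_to_var: dict[str, str] = {}
    for g in genes:
        fam = superfamily_map.get(g)
        if fam is None:
            variables.append(g)
            gene_to_var[g] = g
        else:
            if not variables or variables[-1] != fam:
                variables.append(fam)
            gene_to_var[g] = fam
    p = len(variables)

    # Chain skeleton over model variables.
    model = PathModel(variables)
    B = np.zeros((p, p))
    edge_sign = {}
    for k in range(p - 1):
        src, tgt = variables[k], variables[k + 1]
        coef = 0.6 if k % 2 == 0 else -0.5
        B[k + 1, k] = coef
        kind = "activation" if coef > 0 else "inhibition"
        model.add_beta(tgt, src, provenance=f"kegg:{kind}")
        edge_sign[(tgt, src)] = kind
    assert not check_bow_free(model) and check_block_recursive(model)[0]

    shifted = [quarters[1], quarters[2]]
    deg_list = sorted({quarters[0], quarters[-1], *shifted})

    # Planted group difference on the last chain edge between plain genes.
    delta_edge = None
    for k in range(p - 2, 0, -1):
        tgt, src = variables[k + 1], variables[k]
        if tgt not in family_members and src not in family_members:
            delta_edge = (tgt, src)
            break
    B1 = B.copy()
    if config.delta_beta:
        i, j = variables.index(delta_edge[0]), variables.index(delta_edge[1])
        B1[i, j] = B[i, j] + config.delta_beta

    # Optional hidden edge: in the truth of both groups, absent from the pathway.
    hidden = None
    if config.hidden_edge_beta:
        src = variables[0]
        tgt = next(
            v
            for v in variables[3:]
            if v not in family_members and (v, variables[0]) not in edge_sign
        )
        hidden = (tgt, src)
        i, j = variables.index(tgt), variables.index(src)
        B1[i, j] += config.hidden_edge_beta
        B2 = B.copy()
        B2[i, j] += config.hidden_edge_beta
    else:
        B2 = B.copy()

    Psi = np.eye(p)
    mu0 = np.full(p, config.baseline_mean)
    nu2 = (np.eye(p) - B2) @ mu0
    # Group 1 keeps the same structural intercepts except the planted node
    # shifts; marginal means downstream of the perturbed edge drift freely,
    # as they would in a real regulatory change.
    nu1 = nu2.copy()
    for s in shifted:
        nu1[variables.index(s)] += config.delta_mu  # one residual SD

    truth1 = SEMParameters(beta=B1, psi=Psi.copy(), means=nu1)
    truth2 = SEMParameters(beta=B2, psi=Psi.copy(), means=nu2)
    for truth in (truth1, truth2):
        implied_covariance(truth)  # validates invertibility
        if np.max(np.abs(np.linalg.eigvals(truth.beta))) >= 1:
            raise ValueError("infeasible config: explosive feedback in the truth")

    # Gene-level pathway: the chain through family members, plus decoys.
    pathway = PathwayGraph()
    for a, b in zip(genes[:-1], genes[1:]):
        va, vb = gene_to_var[a], gene_to_var[b]
        if va == vb:
            kind = "binding"  # intra-family link
        else:
            kind = edge_sign.get((vb, va), "activation")
        pathway.add_edge(a, b, kind)
    rngd = np.random.default_rng(config.seed + 1)
    anchors = rngd.choice(len(genes) - 2, size=config.n_decoys, replace=True) + 1
    for d in range(config.n_decoys):
        name = f"D{d + 1:02d}"
        anchor = genes[int(anchors[d])]
        if d % 2 == 0:
            pathway.add_edge(anchor, name, "binding")  # dead end
        else:
            pathway.add_edge(name, anchor, "indirect")  # upstream source
    evidence_pairs = set()
    if hidden is not None:
        ghidden = tuple(hidden)
        evidence_pairs.add(frozenset(ghidden))
    evidence_pairs.add(frozenset((genes[0], genes[-1])))  # decoy evidence pair
    evidence = EvidenceSet(string_edges=evidence_pairs, pathway=pathway)

    return SyntheticScenario(
        config=config,
        variables=variables,
        genes=genes,
        pathway=pathway,
        deg_list=deg_list,
        superfamily_map=superfamily_map,
        evidence=evidence,
        truth_group1=truth1,
        truth_group2=truth2,
        model=model,
        family_members=family_members,
        shifted_nodes=shifted,
        delta_beta_edge=delta_edge,
        hidden_edge=hidden,
    )
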