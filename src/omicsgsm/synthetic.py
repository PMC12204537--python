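"""Synthetic three-layer omics generator with planted regulatory modules.

Real multi-omics integration data cannot ship with the package, so tests
and demonstrations run on generated matrices that reproduce the features
the pipeline relies on: miRNAs anti-correlated with the genes they
repress, CpG sites correlated with the genes they regulate, and
class-discriminative gene modules.

A planted module consists of ``n_genes`` genes sharing a latent factor
(giving pairwise correlation ~rho), ``n_mirnas`` miRNA rows built as a
negative linear transform of the module-gene mean plus noise, and
``n_cpgs`` CpG rows built as a positive transform of the same mean.
Discriminative modules shift their gene means by ``delta`` standard
deviations between the two classes, which propagates to the coupled
miRNA/CpG rows.  Background rows are independent Gaussian noise.
Methylation values are optionally squashed through a logistic to (0,1)
to mimic beta values (monotone, so rank correlations are untouched).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import OmicsMatrix, SampleLabels


@dataclass
class PlantedModule:
    n_genes: int = 3
    n_mirnas: int = 1
    n_cpgs: int = 1
    rho: float = 0.9          # within-module gene-gene correlation
    delta: float = 2.0        # between-class gene mean shift, in SD units
    discriminative: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.rho < 1:
            raise ValueError(f"rho must lie in (0,1), got {self.rho}")
        if min(self.n_genes, self.n_mirnas, self.n_cpgs) < 1:
            raise ValueError("a planted module needs >= 1 gene, miRNA and CpG")


@dataclass
class SyntheticSpec:
    """Study conditions for a generated dataset.

    Defaults give 100 samples per class, one strongly coupled
    discriminative module (rho 0.9, delta 2) and modest independent
    background in each layer — enough background for spurious
    correlations to be possible in principle but not expected at the
    default correlation threshold.
    """

    n_samples_per_class: int = 100
    n_genes: int = 200
    n_mirnas: int = 30
    n_cpgs: int = 30
    planted_modules: list[PlantedModule] = field(default_factory=lambda: [PlantedModule()])
    noise_sd: float = 0.5     # coupling noise on miRNA/CpG rows
    squash_methylation: bool = True
    class_names: tuple[str, str] = ("HR+", "HR-")
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_genes, self.n_mirnas, self.n_cpgs, self.n_samples_per_class) < 0:
            raise ValueError("counts must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        for m in self.planted_modules:
            if m.n_genes > self.n_genes or m.n_mirnas > self.n_mirnas or m.n_cpgs > self.n_cpgs:
                raise ValueError("planted module larger than its layer")
        if sum(m.n_genes for m in self.planted_modules) > self.n_genes:
            raise ValueError("planted modules exceed the gene count")
        if sum(m.n_mirnas for m in self.planted_modules) > self.n_mirnas:
            raise ValueError("planted modules exceed the miRNA count")
        if sum(m.n_cpgs for m in self.planted_modules) > self.n_cpgs:
            raise ValueError("planted modules exceed the CpG count")


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def generate_multiomics(
    spec: SyntheticSpec,
) -> tuple[tuple[OmicsMatrix, OmicsMatrix, OmicsMatrix], SampleLabels, dict]:
    """Generate (mRNA, miRNA, CpG) matrices, labels and the ground truth.

    The ground truth lists, per module, its gene/miRNA/CpG ids and the
    name of the pro-group the pipeline is expected to recover (all the
    module's miRNA x CpG pairs share the module gene list, so they merge
    into a single pro-group).
    """
    rng = np.random.default_rng(spec.seed)
    n = 2 * spec.n_samples_per_class
    sample_ids = [f"s{i:04d}" for i in range(n)]
    y = np.array([spec.class_names[0]] * spec.n_samples_per_class
                 + [spec.class_names[1]] * spec.n_samples_per_class)

    gene_ids = [f"g{i:04d}" for i in range(spec.n_genes)]
    mirna_ids = [f"mir-{i:03d}" for i in range(spec.n_mirnas)]
    cpg_ids = [f"cg{i:07d}" for i in range(spec.n_cpgs)]

    genes = rng.standard_normal((spec.n_genes, n))
    mirnas = rng.standard_normal((spec.n_mirnas, n))
    cpgs = rng.standard_normal((spec.n_cpgs, n))

    gi = mi = ci = 0
    truth_modules = []
    for k, mod in enumerate(spec.planted_modules):
        factor = rng.standard_normal(n)
        shift = np.where(y == spec.class_names[0], mod.delta / 2, -mod.delta / 2) \
            if mod.discriminative else 0.0
        g_rows = slice(gi, gi + mod.n_genes)
        eps = rng.standard_normal((mod.n_genes, n))
        genes[g_rows] = np.sqrt(mod.rho) * factor + np.sqrt(1 - mod.rho) * eps + shift
        gene_mean = genes[g_rows].mean(axis=0)
        for j in range(mod.n_mirnas):
            mirnas[mi + j] = -gene_mean + spec.noise_sd * rng.standard_normal(n)
        for j in range(mod.n_cpgs):
            cpgs[ci + j] = gene_mean + spec.noise_sd * rng.standard_normal(n)
        mod_genes = gene_ids[gi:gi + mod.n_genes]
        mod_mirnas = mirna_ids[mi:mi + mod.n_mirnas]
        mod_cpgs = cpg_ids[ci:ci + mod.n_cpgs]
        pair_names = sorted(f"{a}_{b}" for a in mod_mirnas for b in mod_cpgs)
        truth_modules.append({
            "module": k,
            "genes": mod_genes,
            "mirnas": mod_mirnas,
            "cpgs": mod_cpgs,
            "discriminative": mod.discriminative,
            "expected_pro_group": ", ".join(pair_names),
        })
        gi += mod.n_genes
        mi += mod.n_mirnas
        ci += mod.n_cpgs

    if spec.squash_methylation:
        cpgs = _logistic(cpgs)

    mk = lambda kind, ids, vals: OmicsMatrix(
        kind, pd.DataFrame(vals, index=ids, columns=sample_ids)
    )
    matrices = (
        mk("mRNA", gene_ids, genes),
        mk("miRNA", mirna_ids, mirnas),
        mk("CpG", cpg_ids, cpgs),
    )
    labels = SampleLabels(pd.Series(y, index=sample_ids, name="class"))
    truth = {"modules": truth_modules, "class_names": list(spec.class_names)}
    return matrices, labels, truth


def write_dataset(spec: SyntheticSpec, out_dir) -> dict:
    """Write the three matrices, labels and ground-truth JSON to a directory."""
    import json
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (mrna, mirna, cpg), labels, truth = generate_multiomics(spec)
    paths = {}
    for name, m in (("mrna", mrna), ("mirna", mirna), ("methylation", cpg)):
        p = out_dir / f"{name}.tsv"
        m.data.to_csv(p, sep="\t")
        paths[name] = str(p)
    lp = out_dir / "labels.tsv"
    labels.labels.rename("class").to_csv(lp, sep="\t", index_label="sample_id")
    paths["labels"] = str(lp)
    tp = out_dir / "ground_truth.json"
    with open(tp, "w") as fh:
        json.dump(truth, fh, indent=2)
    paths["ground_truth"] = str(tp)
    return paths
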