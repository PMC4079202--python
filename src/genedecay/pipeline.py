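"""End-to-end study orchestration: scan -> classify -> dN/dS -> model fits.

A *study* is a set of genes, each with a codon alignment and a designated
reference, plus one species tree and one species manifest.  The report
mirrors the two summary artifacts of a gene-loss survey: a genes-by-species
status matrix (+ / - / . / sharing-class codes) and a model-comparison table
(omega per branch class, lnL, LRT statistic, df, p, significance at 0.05).
P-values are reported raw; a Benjamini–Hochberg column is emitted for
reference but never drives the significance flag.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from genedecay import __version__
from genedecay.core import (
    label_whale_branches,
    read_alignment,
    read_manifest,
    read_tree,
)
from genedecay.dnds import DnDsConfig, alignment_pairwise_table
from genedecay.errors import GenedecayError, InsufficientDataError
from genedecay.likelihood import NULL_OF, FitOptions, fit_ladder
from genedecay.orf import (
    call_gene_status,
    detect_disruptions,
    events_table,
    group_and_classify,
    status_matrix_row,
)
from genedecay.gy94 import sanitize_for_model


@dataclass
class GeneInput:
    alignment_path: str
    reference_id: str


@dataclass
class StudyConfig:
    genes: dict[str, GeneInput]
    tree_path: str
    manifest_path: str
    out_dir: str
    dnds_R: float = 2.0
    dnds_pairs: list[tuple[str, str]] | None = None
    schemes: list[str] = field(default_factory=lambda: ["one_ratio", "stem_two_ratio"])
    fix_branch_lengths: bool = False
    label_clades: bool = True       # derive stem/toothed/baleen branch classes
    seed: int = 0
    alpha: float = 0.05

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        raw = yaml.safe_load(Path(path).read_text())
        genes = {
            name: GeneInput(
                alignment_path=spec["alignment"], reference_id=spec["reference"]
            )
            for name, spec in raw["genes"].items()
        }
        dnds = raw.get("dnds", {})
        models = raw.get("models", {})
        return cls(
            genes=genes,
            tree_path=raw["tree"],
            manifest_path=raw["manifest"],
            out_dir=raw.get("out_dir", "genedecay_out"),
            dnds_R=float(dnds.get("R", 2.0)),
            dnds_pairs=[tuple(p) for p in dnds["pairs"]] if "pairs" in dnds else None,
            schemes=list(models.get("schemes", ["one_ratio", "stem_two_ratio"])),
            fix_branch_lengths=bool(models.get("fix_branch_lengths", False)),
            label_clades=bool(raw.get("label_clades", True)),
            seed=int(raw.get("seed", 0)),
            alpha=float(raw.get("alpha", 0.05)),
        )

    def validate(self) -> None:
        if not self.genes:
            raise GenedecayError("study config lists no genes")
        for name, g in self.genes.items():
            if not Path(g.alignment_path).exists():
                raise GenedecayError(f"alignment for {name} missing: {g.alignment_path}")
        for p in (self.tree_path, self.manifest_path):
            if not Path(p).exists():
                raise GenedecayError(f"input file missing: {p}")
        for s in self.schemes:
            if s != "one_ratio" and NULL_OF.get(s) not in self.schemes:
                raise GenedecayError(
                    f"scheme {s} has no declared null in the scheme list"
                )

    def digest(self) -> str:
        payload = json.dumps(
            {
                "genes": {k: vars(v) for k, v in sorted(self.genes.items())},
                "tree": self.tree_path, "manifest": self.manifest_path,
                "R": self.dnds_R, "pairs": self.dnds_pairs,
                "schemes": self.schemes, "fix_bl": self.fix_branch_lengths,
                "seed": self.seed, "alpha": self.alpha,
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class StudyReport:
    status_matrix: pd.DataFrame
    events: pd.DataFrame
    dnds: pd.DataFrame
    model_fits: pd.DataFrame
    warnings: list[str]
    provenance: dict

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.status_matrix.to_csv(out / "status_matrix.tsv", sep="\t", index=True)
        self.events.to_csv(out / "events.tsv", sep="\t", index=False)
        self.dnds.to_csv(out / "dnds.tsv", sep="\t", index=False)
        self.model_fits.to_csv(out / "model_fits.tsv", sep="\t", index=False)
        (out / "provenance.json").write_text(
            json.dumps(self.provenance, indent=1, sort_keys=True) + "\n"
        )
        if self.warnings:
            (out / "warnings.txt").write_text("\n".join(self.warnings) + "\n")


def _bh_adjust(pvals: list[float]) -> list[float]:
    p = np.asarray(pvals, dtype=float)
    n = len(p)
    if n == 0:
        return []
    order = np.argsort(p)
    adj = np.empty(n)
    running = 1.0
    for rank_from_end, idx in enumerate(order[::-1]):
        rank = n - rank_from_end
        running = min(running, p[idx] * n / rank)
        adj[idx] = running
    return adj.tolist()


def run_study(config: StudyConfig, write: bool = True) -> StudyReport:
    """Run the full inference chain and assemble the report tables.

    Stages per gene: disruption scan -> grouping/classification -> status
    calls -> pairwise dN/dS -> sanitization -> branch-model fits -> LRTs.
    Deterministic given the config (fits are seeded); re-running writes
    byte-identical tables.
    """
    config.validate()
    tree = read_tree(config.tree_path)
    manifest = read_manifest(config.manifest_path)
    if config.label_clades:
        label_whale_branches(tree, manifest)
    species_order = manifest.species_ids
    warnings: list[str] = []
    status_rows: dict[str, list[str]] = {}
    event_frames, dnds_frames, model_rows = [], [], []

    for gene in sorted(config.genes):
        gin = config.genes[gene]
        aln = read_alignment(gin.alignment_path, gin.reference_id)
        scan = detect_disruptions(aln, code=DnDsConfig().code, gene=gene)
        grouped, near = group_and_classify(scan.disruptions, manifest)
        warnings += [f"{gene}: {w}" for w in near]
        call = call_gene_status(aln, manifest, grouped, gene)
        status_rows[gene] = status_matrix_row(call, species_order)
        event_frames.append(events_table(gene, grouped, tree=tree))

        tab = alignment_pairwise_table(
            aln, pairs=config.dnds_pairs, config=DnDsConfig(R=config.dnds_R)
        )
        tab.insert(0, "gene", gene)
        dnds_frames.append(tab)
        if "omega" in tab.columns:
            n_undef = int(tab["omega"].isna().sum())
            if n_undef:
                warnings.append(f"{gene}: {n_undef} pair(s) with dS=0, omega undefined")

        try:
            matrix, taxa, removal_log = sanitize_for_model(aln)
        except InsufficientDataError as exc:
            warnings.append(f"{gene}: model fitting skipped ({exc})")
            continue
        opts = FitOptions(
            fix_branch_lengths=config.fix_branch_lengths, seed=config.seed
        )
        fits, tests = fit_ladder(matrix, taxa, tree, config.schemes, opts)
        for scheme in config.schemes:
            fit = fits[scheme]
            test = tests.get(scheme)
            model_rows.append({
                "gene": gene,
                "scheme": scheme,
                "omega": ";".join(
                    f"{k}={v:.4f}" for k, v in fit.params.omega_by_class.items()
                ),
                "kappa": round(fit.params.kappa, 4),
                "lnL": round(fit.lnL, 4),
                "n_free_params": fit.n_free_params,
                "comparison": f"{scheme} vs {NULL_OF[scheme]}" if test else "",
                "stat": round(test.stat, 4) if test else np.nan,
                "df": test.df if test else np.nan,
                "p": test.p if test else np.nan,
                "n_codons_removed": len(removal_log),
            })
            if fit.convergence.get("restarts", 0) and not fit.convergence.get("success"):
                warnings.append(f"{gene}/{scheme}: optimizer reported non-success")

    status_matrix = pd.DataFrame.from_dict(
        status_rows, orient="index", columns=species_order
    )
    status_matrix.index.name = "gene"
    model_fits = pd.DataFrame(model_rows)
    if not model_fits.empty:
        tested = model_fits["p"].notna()
        model_fits["significant_0.05"] = (model_fits["p"] < config.alpha) & tested
        bh = pd.Series(np.nan, index=model_fits.index)
        bh[tested] = _bh_adjust(model_fits.loc[tested, "p"].tolist())
        model_fits["p_bh"] = bh
    report = StudyReport(
        status_matrix=status_matrix,
        events=pd.concat(event_frames, ignore_index=True)
        if event_frames else pd.DataFrame(),
        dnds=pd.concat(dnds_frames, ignore_index=True)
        if dnds_frames else pd.DataFrame(),
        model_fits=model_fits,
        warnings=warnings,
        provenance={
            "package_version": __version__,
            "config_digest": config.digest(),
            "seed": config.seed,
        },
    )
    if write:
        report.write(config.out_dir)
    return report


def render_status_matrix(report: StudyReport) -> str:
    """Plain-text grid of the status matrix (cells +, -, ., S, S*, S#, U)."""
    df = report.status_matrix
    widths = [max(len(str(c)), 2) for c in df.columns]
    gene_w = max([len(str(g)) for g in df.index] + [4])
    lines = [
        " ".join(["gene".ljust(gene_w)] + [str(c).rjust(w) for c, w in zip(df.columns, widths)])
    ]
    for gene, row in df.iterrows():
        lines.append(
            " ".join([str(gene).ljust(gene_w)] + [str(v).rjust(w) for v, w in zip(row, widths)])
        )
    return "\n".join(lines)
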