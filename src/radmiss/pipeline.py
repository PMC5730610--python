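"""End-to-end experiment: simulate/load -> filter family -> statistics ->
resampling -> PCA, with TSV reports and a provenance manifest.

Every output table lives under the run's output directory next to
``manifest.json``, which records the full configuration, its hash, the
seed, and one log line per stage (input shape, output shape, elapsed
time).  Filtered matrices are serialised under ``intermediates/`` so a rerun
with ``resume=True`` can skip completed stages.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .filtering import build_dataset_family, filter_maf, select_single_snp
from .io import read_matrix_tsv, read_popmap, read_vcf, write_matrix_tsv
from .matrix import GenotypeMatrix
from .pca import pca_genotypes
from .popstats import (
    locus_components,
    multilocus_stats,
    pairwise_one_vs_rest,
    per_location_stats,
    stat_histogram,
)
from .resampling import bootstrap_ci, subsample_experiment
from .simulate import SimConfig, apply_allelic_dropout, simulate_snp_panel

__all__ = ["RunConfig", "run_full_experiment"]


@dataclass
class RunConfig:
    """Validated configuration of a full experiment run."""

    out_dir: str
    # input: either a matrix file (+ popmap for VCF) or a simulation block
    input_path: str | None = None
    popmap_path: str | None = None
    simulate: dict | None = None          # SimConfig field overrides
    dropout: bool = True                  # only for simulated input
    dropout_q_range: tuple[float, float] = (0.0, 0.5)
    single_snp: bool = True
    maf_min: float = 0.05
    cutoffs: list[int] = field(default_factory=list)  # default set from N
    estimator: str = "nei"
    bootstrap_B: int = 1000
    alpha: float = 0.05
    subsample_reps: int = 100
    pca_components: int = 4
    pca_scaling: str = "unit"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.input_path is None and self.simulate is None:
            self.simulate = {}
        if self.input_path is not None and self.simulate is not None:
            raise ValueError("give either input_path or simulate, not both")
        if self.estimator not in ("nei", "wc"):
            raise ValueError("estimator must be 'nei' or 'wc'")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        if "dropout_q_range" in data:
            data["dropout_q_range"] = tuple(data["dropout_q_range"])
        return cls(**data)

    def config_hash(self) -> str:
        """Hash of the scientific configuration (output location excluded)."""
        fields = {k: v for k, v in asdict(self).items() if k != "out_dir"}
        blob = json.dumps(fields, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _load_or_simulate(cfg: RunConfig) -> GenotypeMatrix:
    if cfg.input_path is not None:
        path = Path(cfg.input_path)
        if path.suffix in (".vcf",):
            if cfg.popmap_path is None:
                raise ValueError("VCF input needs popmap_path")
            return read_vcf(path, read_popmap(cfg.popmap_path))
        return read_matrix_tsv(path)
    sim_cfg = SimConfig(seed=cfg.seed, **(cfg.simulate or {}))
    gm, truth = simulate_snp_panel(sim_cfg)
    if cfg.dropout:
        gm, _ = apply_allelic_dropout(
            gm, truth, q_law=cfg.dropout_q_range, seed=cfg.seed
        )
    return gm


def _write(df: pd.DataFrame, path: Path, cfg_hash: str) -> None:
    with path.open("w") as fh:
        fh.write(f"# config_hash={cfg_hash}\n")
        df.to_csv(fh, sep="\t", index=False)


def run_full_experiment(cfg: RunConfig, resume: bool = False) -> dict:
    """Run every stage of the experiment; returns the manifest dict.

    Stages: acquire matrix; single-SNP + MAF filter; completeness family;
    per-member multilocus stats with bootstrap CIs, one-vs-rest pairwise
    fst, per-location ho/fis, per-locus fst/fis/ho histograms; locus
    subsampling from the least-filtered member at each member's size; PCA
    per member.  Any stage failure raises with the stage name; previously
    written outputs are preserved.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    inter = out / "intermediates"
    inter.mkdir(exist_ok=True)
    cfg_hash = cfg.config_hash()
    manifest: dict = {
        "config": asdict(cfg),
        "config_hash": cfg_hash,
        "version": __version__,
        "stages": [],
    }

    def log_stage(name: str, t0: float, in_shape, out_shape) -> None:
        manifest["stages"].append(
            {
                "stage": name,
                "input_shape": in_shape,
                "output_shape": out_shape,
                "elapsed_s": round(time.time() - t0, 3),
            }
        )

    stage = "acquire"
    try:
        t0 = time.time()
        src_path = inter / "source.tsv"
        if resume and src_path.exists():
            gm = read_matrix_tsv(src_path)
        else:
            gm = _load_or_simulate(cfg)
            write_matrix_tsv(gm, src_path)
        log_stage(stage, t0, None, (gm.n_individuals, gm.n_loci))

        stage = "prefilter"
        t0 = time.time()
        pre = gm
        if cfg.single_snp and pre.tags is not None:
            pre = select_single_snp(pre)
        if cfg.maf_min > 0:
            pre = filter_maf(pre, cfg.maf_min)
        log_stage(
            stage,
            t0,
            (gm.n_individuals, gm.n_loci),
            (pre.n_individuals, pre.n_loci),
        )

        stage = "family"
        t0 = time.time()
        n = pre.n_individuals
        cutoffs = cfg.cutoffs or sorted(
            {1, round(0.3 * n), round(0.5 * n), round(0.8 * n)}
        )
        family = build_dataset_family(pre, cutoffs)
        summary = family.summary()
        _write(summary, out / "family_summary.tsv", cfg_hash)
        for cutoff, member in family:
            write_matrix_tsv(member, inter / f"family_cutoff{cutoff}.tsv")
        log_stage(stage, t0, (n, pre.n_loci), list(summary["n_loci"]))

        stage = "stats"
        t0 = time.time()
        comps_by_cutoff = {}
        stat_rows, pair_rows, loc_rows, hist_rows = [], [], [], []
        for cutoff, member in family:
            comps = locus_components(member)
            comps_by_cutoff[cutoff] = comps
            ml = multilocus_stats(comps)
            ci = bootstrap_ci(
                comps, "fst", B=cfg.bootstrap_B, alpha=cfg.alpha, seed=cfg.seed
            )
            stat_rows.append(
                {
                    "cutoff": cutoff,
                    "n_loci": member.n_loci,
                    "ho": ml.ho_bar,
                    "he": ml.hs_bar,
                    "ht": ml.ht_bar,
                    "fst": ml.fst,
                    "fst_ci_low": ci.ci_low,
                    "fst_ci_high": ci.ci_high,
                    "fis": ml.fis,
                    "n_loci_used": ml.n_loci_used,
                }
            )
            for pop in member.pop_labels:
                pair_rows.append(
                    {
                        "cutoff": cutoff,
                        "population": pop,
                        "fst_one_vs_rest": pairwise_one_vs_rest(member, pop),
                    }
                )
            for pop, ls in per_location_stats(member).items():
                loc_rows.append(
                    {
                        "cutoff": cutoff,
                        "population": pop,
                        "ho": ls.ho,
                        "fis": ls.fis,
                    }
                )
            for name, vals in (
                ("fst", comps.fst),
                ("fis", comps.fis),
                ("ho", comps.ho),
            ):
                h = stat_histogram(vals)
                for lo, c in zip(h.bin_lo, h.counts):
                    hist_rows.append(
                        {
                            "cutoff": cutoff,
                            "statistic": name,
                            "bin_lo": round(float(lo), 6),
                            "count": int(c),
                        }
                    )
                hist_rows.append(
                    {
                        "cutoff": cutoff,
                        "statistic": name,
                        "bin_lo": "extreme>0.975",
                        "count": h.extreme_count,
                    }
                )
        _write(pd.DataFrame(stat_rows), out / "multilocus_stats.tsv", cfg_hash)
        _write(pd.DataFrame(pair_rows), out / "pairwise_fst.tsv", cfg_hash)
        _write(pd.DataFrame(loc_rows), out / "location_stats.tsv", cfg_hash)
        _write(pd.DataFrame(hist_rows), out / "locus_histograms.tsv", cfg_hash)
        log_stage(stage, t0, len(family.members), len(stat_rows))

        stage = "subsample"
        t0 = time.time()
        full_cutoff = min(c for c, _ in family)
        full_comps = comps_by_cutoff[full_cutoff]
        sizes = sorted(
            {
                member.n_loci
                for c, member in family
                if c != full_cutoff and member.n_loci >= 1
            }
        )
        sub_rows = []
        if sizes:
            results = subsample_experiment(
                full_comps,
                sizes=sizes,
                reps=cfg.subsample_reps,
                seed=cfg.seed,
                bootstrap_B=cfg.bootstrap_B,
                alpha=cfg.alpha,
            )
            for size, res in results.items():
                sub_rows.append(
                    {
                        "size": size,
                        "mean_fst": res.mean,
                        "ci_low": res.result.ci_low,
                        "ci_high": res.result.ci_high,
                        "full_estimate": res.result.point_estimate,
                        "frac_inside_full_ci": res.frac_inside_full_ci,
                        "overlap_with_full": res.overlap_with_full,
                    }
                )
        _write(pd.DataFrame(sub_rows), out / "subsampling.tsv", cfg_hash)
        log_stage(stage, t0, sizes, len(sub_rows))

        stage = "pca"
        t0 = time.time()
        n_pca = 0
        for cutoff, member in family:
            if member.n_loci == 0:
                continue
            res = pca_genotypes(
                member, n_components=cfg.pca_components, scaling=cfg.pca_scaling
            )
            df = pd.DataFrame(
                res.coordinates,
                columns=[f"PC{i + 1}" for i in range(res.n_components)],
            )
            df.insert(0, "individual", res.individual_ids)
            df.insert(1, "population", res.populations)
            path = out / f"pca_cutoff{cutoff}.tsv"
            with path.open("w") as fh:
                fh.write(f"# config_hash={cfg_hash}\tscaling={res.scaling}\n")
                fh.write(
                    "# explained_variance="
                    + ",".join(f"{v:.6g}" for v in res.explained_variance)
                    + "\n"
                )
                df.to_csv(fh, sep="\t", index=False)
            n_pca += 1
        log_stage(stage, t0, len(family.members), n_pca)
    except Exception as exc:
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
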