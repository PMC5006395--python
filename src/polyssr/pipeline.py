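"""End-to-end pipeline: matrix (read or simulate) -> diversity report ->
distances -> supported dendrogram -> k-means cascade -> PCA.

A single structured config drives everything so a run can be replayed
exactly; all stochastic stages take explicit integer seeds and every output
is a plain TSV/Newick/YAML text file.  Given the same config and seeds the
output bundle is byte-identical across runs (wall-clock timings are logged
to the console, not into the bundle).
"""

from __future__ import annotations

import logging
import time
from dataclasses import asdict, dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import __version__
from .diversity import marker_summaries, panel_summary, private_allele_stats
from .distance import euclidean_binary, modified_rogers
from .matrix import AlleleMatrix, read_allele_matrix, write_allele_matrix
from .simulate import SimConfig, simulate_panel
from .structure import (
    DEFAULT_SCALES,
    kmeans_cascade,
    multiscale_bootstrap_support,
    pca_binary,
)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "make_table3_report", "round_half_up"]

log = logging.getLogger("polyssr")


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and the offending record."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage {stage!r}: {message}")


def round_half_up(x: float, decimals: int = 2) -> float:
    """Decimal round-half-up (report convention; 0.125 -> 0.13 at 2 dp)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class PipelineConfig:
    """Everything a run needs; exactly one of ``input_matrix``/``simulate``."""

    input_matrix: str | None = None
    simulate: SimConfig | None = None
    metric: str = "rogers"  # rogers | euclidean
    linkage: str = "average"
    scales: tuple[float, ...] = DEFAULT_SCALES
    bootstrap_B: int = 1000
    bootstrap_seed: int = 0
    bootstrap_unit: str = "allele"
    k_min: int = 2
    k_max: int = 10
    kmeans_restarts: int = 10
    kmeans_seed: int = 0
    report_decimals: int = 2
    run_bootstrap: bool = True

    def validate(self) -> None:
        if (self.input_matrix is None) == (self.simulate is None):
            raise ValueError("config must provide exactly one of input matrix / simulate block")
        if self.metric not in ("rogers", "euclidean"):
            raise ValueError(f"unknown metric {self.metric!r}")

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        d = dict(d)
        sim = d.pop("simulate", None)
        cfg = cls(simulate=SimConfig(**sim) if sim is not None else None, **d)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self) -> str:
        d = asdict(self)
        d["scales"] = [float(s) for s in self.scales]
        if self.simulate is not None:
            d["simulate"]["group_sizes"] = list(self.simulate.group_sizes)
            d["simulate"]["alleles_per_locus"] = list(self.simulate.alleles_per_locus)
        return yaml.safe_dump(d, sort_keys=True)


def make_table3_report(summaries, decimals: int = 2) -> str:
    """Marker characterisation table as TSV text.

    One row per marker with the columns Marker, PIC_Av, PIC_Min, PIC_Max,
    NoA, NoA_Priv, MinAF, MaxAF, Size (size range as ``min-max`` bp), PIC
    and frequency values rounded half-up, plus a TOTAL footer with the
    panel totals (total alleles, mean per marker, total private).
    """
    df = summaries if hasattr(summaries, "iterrows") else marker_summaries(summaries)
    if len(df) == 0:
        raise ValueError("no marker summaries to report")
    lines = ["Marker\tPIC_Av\tPIC_Min\tPIC_Max\tNoA\tNoA_Priv\tMinAF\tMaxAF\tSize"]
    fmt = f"{{:.{decimals}f}}"
    for marker_id, r in df.iterrows():
        lines.append(
            "\t".join(
                [
                    str(marker_id),
                    fmt.format(round_half_up(r["pic_av"], decimals)),
                    fmt.format(round_half_up(r["pic_min"], decimals)),
                    fmt.format(round_half_up(r["pic_max"], decimals)),
                    str(int(r["noa_tot"])),
                    str(int(r["noa_priv"])),
                    fmt.format(round_half_up(r["min_af"], decimals)),
                    fmt.format(round_half_up(r["max_af"], decimals)),
                    f"{int(r['size_min_bp'])}-{int(r['size_max_bp'])}",
                ]
            )
        )
    total = int(df["noa_tot"].sum())
    priv = int(df["noa_priv"].sum())
    mean_per_marker = total / len(df)
    lines.append(
        f"TOTAL\t{fmt.format(round_half_up(df['pic_av'].mean(), decimals))}\t\t\t"
        f"{total}\t{priv}\t\t\tmean_alleles_per_marker={round_half_up(mean_per_marker, 1)}"
    )
    return "\n".join(lines) + "\n"


def run_pipeline(cfg: PipelineConfig, out_dir) -> dict[str, Path]:
    """Execute all stages and write the report bundle into ``out_dir``.

    Returns a name -> path map of the written outputs.  On a stage failure
    all partial outputs are removed and a :class:`PipelineError` naming the
    stage propagates.
    """
    cfg.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    def emit(name: str, filename: str, text: str) -> None:
        p = out / filename
        p.write_text(text, encoding="utf-8")
        written[name] = p

    t0 = time.perf_counter()
    stage = "config"
    try:
        emit("config", "config.yaml", cfg.to_yaml())

        stage = "input"
        if cfg.simulate is not None:
            matrix, truth = simulate_panel(cfg.simulate)
            write_allele_matrix(matrix, out / "allele_matrix.tsv")
            written["allele_matrix"] = out / "allele_matrix.tsv"
            truth_lines = ["individual_id\tgroup"]
            truth_lines += [f"{i}\t{g + 1}" for i, g in truth.group_labels.items()]
            emit("sim_truth", "sim_truth.tsv", "\n".join(truth_lines) + "\n")
        else:
            matrix = read_allele_matrix(cfg.input_matrix)
        log.info(
            "panel: n=%d individuals, A=%d alleles, L=%d loci",
            matrix.n, matrix.n_alleles, matrix.n_loci,
        )

        stage = "diversity"
        summaries = marker_summaries(matrix)
        emit("marker_summary", "marker_summary.tsv", make_table3_report(summaries, cfg.report_decimals))
        psum = panel_summary(matrix)
        priv = private_allele_stats(matrix)
        panel_lines = [
            "key\tvalue",
            f"total_alleles\t{psum.total_alleles}",
            f"n_loci\t{psum.n_loci}",
            f"mean_alleles_per_marker\t{round_half_up(psum.mean_alleles_per_marker, 1)}",
            f"mean_alleles_per_individual\t{round_half_up(psum.mean_alleles_per_individual, 1)}",
            f"mean_alleles_per_individual_per_marker\t"
            f"{round_half_up(psum.mean_alleles_per_individual_per_marker, 1)}",
            f"total_private_alleles\t{psum.total_private}",
        ]
        emit("panel_summary", "panel_summary.tsv", "\n".join(panel_lines) + "\n")
        emit(
            "private_per_individual",
            "private_per_individual.tsv",
            "individual_id\tn_private\n"
            + "".join(f"{i}\t{v}\n" for i, v in priv.per_individual.items()),
        )
        emit(
            "missingness",
            "missingness.tsv",
            matrix.missingness_report().to_csv(sep="\t"),
        )

        stage = "distance"
        eu = euclidean_binary(matrix)
        dw = modified_rogers(matrix)
        eu.to_tsv(out / "dist_euclidean.tsv")
        dw.to_tsv(out / "dist_rogers.tsv")
        dw.to_phylip(out / "dist_rogers.dist")
        written["dist_euclidean"] = out / "dist_euclidean.tsv"
        written["dist_rogers"] = out / "dist_rogers.tsv"
        written["dist_rogers_phylip"] = out / "dist_rogers.dist"
        log.info("D_w observed range: %.3f .. %.3f", *dw.observed_range())

        if cfg.run_bootstrap:
            stage = "bootstrap"
            dendro = multiscale_bootstrap_support(
                matrix,
                scales=cfg.scales,
                B=cfg.bootstrap_B,
                seed=cfg.bootstrap_seed,
                unit=cfg.bootstrap_unit,
                linkage_method=cfg.linkage,
            )
            emit("dendrogram", "dendrogram.nwk", dendro.to_newick() + "\n")
            emit("dendrogram_support", "dendrogram_support.tsv", dendro.to_table().to_csv(sep="\t"))

        stage = "kmeans"
        part = kmeans_cascade(
            matrix,
            k_min=cfg.k_min,
            k_max=cfg.k_max,
            restarts=cfg.kmeans_restarts,
            seed=cfg.kmeans_seed,
        )
        emit("partitions", "partitions.tsv", part.to_dataframe(matrix.individuals).to_csv(sep="\t"))
        ch_lines = ["k\tcalinski"] + [
            f"{k}\t{part.ch_by_k[k]:.6f}" for k in part.k_range
        ]
        ch_lines.append(f"best_k\t{part.best_k}")
        emit("calinski", "calinski.tsv", "\n".join(ch_lines) + "\n")
        log.info("Calinski cascade: best_k=%d", part.best_k)

        stage = "pca"
        pca = pca_binary(matrix)
        scores = pca.to_dataframe()
        emit("pca_scores", "pca_scores.tsv", scores.to_csv(sep="\t", float_format="%.6f"))
        var_lines = ["component\tpct_var"] + [
            f"PC{i + 1}\t{v:.4f}" for i, v in enumerate(pca.pct_var)
        ]
        emit("pca_variance", "pca_variance.tsv", "\n".join(var_lines) + "\n")

        stage = "log"
        log_lines = [
            f"polyssr\t{__version__}",
            f"numpy\t{np.__version__}",
            f"n_individuals\t{matrix.n}",
            f"n_alleles\t{matrix.n_alleles}",
            f"n_loci\t{matrix.n_loci}",
            f"bootstrap_seed\t{cfg.bootstrap_seed}",
            f"kmeans_seed\t{cfg.kmeans_seed}",
            f"simulate_seed\t{cfg.simulate.seed if cfg.simulate else 'NA'}",
        ]
        emit("run_log", "run_log.tsv", "\n".join(log_lines) + "\n")
    except Exception as exc:
        for p in written.values():
            p.unlink(missing_ok=True)
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(stage, str(exc)) from exc

    log.info("pipeline finished in %.1f s", time.perf_counter() - t0)
    return written
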