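"""Summary tables over called sites, and the end-to-end pipeline driver.

The packaged fixtures transcribe the printed per-sample site counts and the
per-gene (sample, gene, conversion, occurrence) table of the emulated study;
a shipped alias map normalises that table's inconsistent gene spellings
before any gene is counted.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from dataclasses import asdict
from importlib import resources
from pathlib import Path
import pandas as pd
import yaml

from . import __version__
from .annotate import annotate_sites
from .io_formats import (
    SampleSheet,
    read_fasta,
    read_gff3,
    sites_to_frame,
    write_site_table,
    write_vcf,
)
from .pileup_detect import DetectionConfig, detect_experiment
from .stats_expr import cluster_row_order, efficiency_matrix
from .synthetic_data import SimulationConfig, simulate_experiment

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Packaged fixtures


def _data_text(name: str) -> str:
    return resources.files("oredit.data").joinpath(name).read_text()


def load_gene_aliases() -> dict[str, str]:
    return yaml.safe_load(_data_text("gene_aliases.yaml"))


def load_site_count_fixture() -> pd.DataFrame:
    """Per-(organelle, sample) site totals."""
    from io import StringIO

    return pd.read_csv(StringIO(_data_text("table2_site_counts.tsv")), sep="\t")


def load_gene_type_fixture(apply_aliases: bool = True) -> pd.DataFrame:
    """Per-(organelle, sample, gene, conversion) occurrence rows."""
    from io import StringIO

    frame = pd.read_csv(StringIO(_data_text("table3_gene_types.tsv")), sep="\t")
    if apply_aliases:
        aliases = load_gene_aliases()
        frame["gene"] = frame["gene"].map(lambda g: aliases.get(g, g))
    return frame


def load_chloroplast_type_fixture() -> pd.DataFrame:
    """Chloroplast site totals per observed conversion."""
    from io import StringIO

    return pd.read_csv(
        StringIO(_data_text("chloroplast_type_counts.tsv")), sep="\t"
    )


# ---------------------------------------------------------------------------
# Aggregations

def _as_site_frame(sites) -> pd.DataFrame:
    if isinstance(sites, pd.DataFrame):
        return sites
    return sites_to_frame(list(sites))


def count_by_sample(sites) -> pd.DataFrame:
    """Site totals per (organelle, sample).

    Accepts annotated sites (one row per site x sample; the contig is the
    organelle) or a pre-aggregated fixture frame carrying a ``total`` column.
    """
    frame = _as_site_frame(sites)
    if frame.empty:
        return pd.DataFrame(columns=["organelle", "sample", "total"])
    if "total" in frame.columns:
        out = frame.groupby(["organelle", "sample"], sort=True)["total"].sum()
    else:
        key = "organelle" if "organelle" in frame.columns else "contig"
        out = (
            frame.groupby([key, "sample"], sort=True)
            .size()
            .rename("total")
        )
        out.index.names = ["organelle", "sample"]
    return out.reset_index()


def count_by_type(sites) -> pd.DataFrame:
    """Site totals per conversion (observed and, where present, biological)."""
    frame = _as_site_frame(sites)
    if frame.empty:
        return pd.DataFrame(columns=["conversion", "kind", "count"])
    if "count" in frame.columns and "conversion" in frame.columns:
        out = frame.groupby("conversion")["count"].sum().reset_index()
        out["kind"] = "observed"
        return out[["conversion", "kind", "count"]]
    pieces = []
    for kind, col in (
        ("observed", "observed_conversion"),
        ("biological", "biological_conversion"),
    ):
        if col in frame.columns:
            counts = frame.groupby(col).size().rename("count").reset_index()
            counts = counts.rename(columns={col: "conversion"})
            counts["kind"] = kind
            pieces.append(counts[["conversion", "kind", "count"]])
    return pd.concat(pieces, ignore_index=True)


def count_edited_genes(
    gene_rows: pd.DataFrame, convention: str = "distinct_gene"
) -> pd.DataFrame:
    """Edited-gene tallies per sample from (sample, gene, type) rows.

    ``distinct_gene`` counts each gene once per sample however many
    conversion types it shows (the mitochondrial convention);
    ``gene_type_entries`` counts (gene, type) entries (the chloroplast
    convention).
    """
    if gene_rows.empty:
        return pd.DataFrame(columns=["sample", "n_genes"])
    if convention == "distinct_gene":
        out = gene_rows.groupby("sample")["gene"].nunique()
    elif convention == "gene_type_entries":
        out = (
            gene_rows.drop_duplicates(["sample", "gene", "type"])
            .groupby("sample")
            .size()
        )
    else:
        raise ValueError(f"unknown convention {convention!r}")
    return out.rename("n_genes").reset_index()


def distribution_reports(sites) -> dict[str, pd.DataFrame]:
    """Per-sample percentage tables: codon position, consequence class, and
    amino-acid trend tallies.  Percentages sum to 100 within rounding."""
    frame = _as_site_frame(sites)
    out: dict[str, pd.DataFrame] = {}

    def percent_table(sub: pd.DataFrame, column: str) -> pd.DataFrame:
        rows = []
        for sample, grp in sub.groupby("sample"):
            counts = grp[column].value_counts()
            for value, n in counts.items():
                rows.append(
                    {
                        "sample": sample,
                        column: value,
                        "count": int(n),
                        "percent": 100.0 * n / len(grp),
                    }
                )
        return pd.DataFrame(rows)

    cds = frame[frame["codon_position"].notna()] if not frame.empty else frame
    out["codon_position"] = percent_table(cds, "codon_position")
    out["consequence"] = (
        percent_table(frame, "consequence") if not frame.empty else pd.DataFrame()
    )
    trend = (
        frame[frame["aa_trend"].astype(bool)] if not frame.empty else frame
    )
    out["aa_trend"] = percent_table(trend, "aa_trend")
    return out


# ---------------------------------------------------------------------------
# Pipeline driver


def _config_hash(*configs) -> str:
    payload = yaml.safe_dump([asdict(c) for c in configs], sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(
    out_dir: str | Path,
    sim_cfg: SimulationConfig | None = None,
    det_cfg: DetectionConfig | None = None,
    fasta: str | Path | None = None,
    gff3: str | Path | None = None,
    sample_sheet: str | Path | SampleSheet | None = None,
    window: int = 5000,
) -> dict:
    """simulate (optional) -> detect -> annotate -> summarize, on disk.

    Either provide ``sim_cfg`` to generate a synthetic experiment, or a
    reference FASTA, GFF3 and sample sheet for existing alignments.  Outputs
    a per-sample VCF + TSV, summary tables, an efficiency matrix with a
    clustered row order, and a machine-readable run manifest.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    det_cfg = det_cfg or DetectionConfig()

    stage = "simulate"
    try:
        if sim_cfg is not None:
            sim = simulate_experiment(sim_cfg, out_dir / "sim")
            genome, genes = sim["genome"], sim["genes"]
            sheet = sim["sample_sheet"]
        else:
            if fasta is None or gff3 is None or sample_sheet is None:
                raise ValueError(
                    "need either sim_cfg or (fasta, gff3, sample_sheet)"
                )
            genome = read_fasta(fasta)[0]
            genes = read_gff3(gff3)
            sheet = (
                sample_sheet
                if isinstance(sample_sheet, SampleSheet)
                else SampleSheet.read(sample_sheet)
            )

        stage = "detect"
        final, stage_log = detect_experiment(sheet, genome, det_cfg)

        stage = "annotate"
        annotated = annotate_sites(final, genome, genes, window=window)

        stage = "summarize"
        write_site_table(annotated, out_dir / "sites.tsv")
        write_vcf(annotated, out_dir / "sites.vcf", [genome])
        by_sample = count_by_sample(annotated)
        by_sample.to_csv(out_dir / "sites_by_sample.tsv", sep="\t", index=False)
        by_type = count_by_type(annotated)
        by_type.to_csv(out_dir / "sites_by_type.tsv", sep="\t", index=False)
        matrix = efficiency_matrix(annotated)
        matrix = matrix.loc[cluster_row_order(matrix)]
        matrix.to_csv(out_dir / "efficiency_matrix.tsv", sep="\t")
        for name, table in distribution_reports(annotated).items():
            table.to_csv(out_dir / f"distribution_{name}.tsv", sep="\t", index=False)

        import numpy, pysam, scipy

        manifest = {
            "package_version": __version__,
            "python": platform.python_version(),
            "numpy": numpy.__version__,
            "scipy": scipy.__version__,
            "pysam": pysam.__version__,
            "seed": sim_cfg.seed if sim_cfg is not None else None,
            "config_hash": _config_hash(
                *( [sim_cfg] if sim_cfg is not None else [] ), det_cfg
            ),
            "detection_config": asdict(det_cfg),
            "stage_counts": stage_log,
        }
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    return {
        "genome": genome,
        "genes": genes,
        "sample_sheet": sheet,
        "final_sites": final,
        "annotated": annotated,
        "stage_log": stage_log,
        "manifest": manifest,
    }
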