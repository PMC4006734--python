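"""File formats and pipeline configuration.

TSV round-trips are lossless; BED export converts the package's 1-based
inclusive intervals to 0-based half-open. A minimal VCF reader (pysam)
accepts biallelic SNP records with a per-sample allele-depth (AD) field.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .genome import GenomeMap, Interval, SnpPanel
from .simulate import ReadCountMatrix

__all__ = [
    "FileFormatError",
    "MalformedHeaderError",
    "UnsortedPositionsError",
    "UnknownChromosomeError",
    "MultiallelicRecordError",
    "write_snp_panel",
    "read_snp_panel",
    "write_genotype_matrix",
    "read_genotype_matrix",
    "write_read_counts",
    "read_read_counts",
    "write_phenotypes",
    "read_phenotypes",
    "write_loci_tsv",
    "write_loci_bed",
    "read_vcf_allele_depths",
    "PipelineConfig",
]


class FileFormatError(ValueError):
    """Base class for file-format problems."""


class MalformedHeaderError(FileFormatError):
    pass


class UnsortedPositionsError(FileFormatError):
    pass


class UnknownChromosomeError(FileFormatError):
    pass


class MultiallelicRecordError(FileFormatError):
    pass


_PANEL_COLS = ["chrom", "pos", "allele_A", "allele_B"]


def write_snp_panel(panel: SnpPanel, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "chrom": panel.chroms,
            "pos": panel.pos,
            "allele_A": panel.allele_a,
            "allele_B": panel.allele_b,
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_snp_panel(path: str | Path, genome: GenomeMap) -> SnpPanel:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    if list(df.columns) != _PANEL_COLS:
        raise MalformedHeaderError(
            f"expected columns {_PANEL_COLS}, got {list(df.columns)}"
        )
    known = set(genome.names)
    bad = set(df["chrom"]) - known
    if bad:
        raise UnknownChromosomeError(f"unknown chromosomes in panel: {sorted(bad)}")
    for chrom, sub in df.groupby("chrom", sort=False):
        if (np.diff(sub["pos"].to_numpy()) <= 0).any():
            raise UnsortedPositionsError(f"positions not strictly increasing on {chrom}")
    return SnpPanel(
        chroms=df["chrom"].to_numpy(dtype=object),
        pos=df["pos"].to_numpy(dtype=np.int64),
        allele_a=df["allele_A"].to_numpy(dtype=object),
        allele_b=df["allele_B"].to_numpy(dtype=object),
        genome=genome,
    )


_CALL_TO_CHAR = {0: "A", 1: "B", -1: "N"}
_CHAR_TO_CALL = {v: k for k, v in _CALL_TO_CHAR.items()}


def write_genotype_matrix(
    calls: np.ndarray, ids: list[str], panel: SnpPanel, path: str | Path
) -> None:
    """Segregants × SNPs matrix of A/B/N characters, columns chrom:pos."""
    cols = [f"{c}:{p}" for c, p in zip(panel.chroms, panel.pos)]
    chars = np.vectorize(_CALL_TO_CHAR.get)(calls)
    pd.DataFrame(chars, index=ids, columns=cols).to_csv(
        path, sep="\t", index_label="segregant"
    )


def read_genotype_matrix(path: str | Path) -> tuple[np.ndarray, list[str], list[str]]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.name != "segregant":
        raise MalformedHeaderError("genotype matrix must be indexed by 'segregant'")
    calls = np.vectorize(_CHAR_TO_CALL.get)(df.to_numpy())
    if (calls == None).any():  # noqa: E711 — vectorize returns object on bad chars
        raise FileFormatError("genotype matrix contains values other than A/B/N")
    return calls.astype(np.int8), list(df.index), list(df.columns)


def write_read_counts(matrix: ReadCountMatrix, panel: SnpPanel, path: str | Path) -> None:
    """Long-format TSV: segregant, chrom, pos, depth_A, depth_B."""
    n_seg, n_snp = matrix.depth_a.shape
    df = pd.DataFrame(
        {
            "segregant": np.repeat(matrix.ids, n_snp),
            "chrom": np.tile(panel.chroms, n_seg),
            "pos": np.tile(panel.pos, n_seg),
            "depth_A": matrix.depth_a.ravel(),
            "depth_B": matrix.depth_b.ravel(),
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_read_counts(
    path: str | Path, panel: SnpPanel, mean_depth: float = 4.0, error_rate: float = 0.005
) -> ReadCountMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    expected = ["segregant", "chrom", "pos", "depth_A", "depth_B"]
    if list(df.columns) != expected:
        raise MalformedHeaderError(f"expected columns {expected}, got {list(df.columns)}")
    ids = list(dict.fromkeys(df["segregant"]))
    n_snp = len(panel)
    if len(df) != len(ids) * n_snp:
        raise FileFormatError("read-count table does not cover segregants × panel")
    da = df["depth_A"].to_numpy(dtype=np.int32).reshape(len(ids), n_snp)
    db = df["depth_B"].to_numpy(dtype=np.int32).reshape(len(ids), n_snp)
    return ReadCountMatrix(
        depth_a=da, depth_b=db, ids=ids, mean_depth=mean_depth, error_rate=error_rate
    )


def write_phenotypes(ids: list[str], phenotypes: list[str], path: str | Path) -> None:
    pd.DataFrame({"segregant": ids, "phenotype": phenotypes}).to_csv(
        path, sep="\t", index=False
    )


def read_phenotypes(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t")
    if list(df.columns) != ["segregant", "phenotype"]:
        raise MalformedHeaderError("phenotype table must have columns segregant, phenotype")
    return dict(zip(df["segregant"], df["phenotype"]))


def write_loci_tsv(loci: list, path: str | Path) -> None:
    rows = [
        {
            "chrom": lc.chrom,
            "start": lc.interval.start,
            "end": lc.interval.end,
            "peak_pos": lc.peak_pos,
            "peak_frequency": lc.peak_frequency,
            "is_fixed": lc.is_fixed,
            "artifact": lc.artifact,
            "n_carriers": lc.n_carriers,
        }
        for lc in loci
    ]
    pd.DataFrame(
        rows,
        columns=[
            "chrom", "start", "end", "peak_pos", "peak_frequency",
            "is_fixed", "artifact", "n_carriers",
        ],
    ).to_csv(path, sep="\t", index=False)


def write_loci_bed(loci: list, path: str | Path) -> None:
    """BED4+1: chrom, 0-based start, half-open end, name, peak frequency."""
    with open(path, "w") as fh:
        for i, lc in enumerate(loci):
            iv: Interval = lc.interval if hasattr(lc, "interval") else lc
            name = f"locus_{i + 1}"
            freq = getattr(lc, "peak_frequency", ".")
            fh.write(f"{iv.chrom}\t{iv.start - 1}\t{iv.end}\t{name}\t{freq}\n")


def read_vcf_allele_depths(
    path: str | Path, genome: GenomeMap, mean_depth: float = 4.0, error_rate: float = 0.005
) -> tuple[SnpPanel, ReadCountMatrix]:
    """Read a minimal VCF with per-sample AD fields.

    Records must be biallelic SNPs; REF is taken as the parent-A allele
    and ALT as parent-B. Multiallelic or indel records raise
    :class:`MultiallelicRecordError`/:class:`FileFormatError`.
    """
    import pysam

    known = set(genome.names)
    chroms: list[str] = []
    pos: list[int] = []
    ref: list[str] = []
    alt: list[str] = []
    depth_rows: list[list[tuple[int, int]]] = []
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        if not samples:
            raise MalformedHeaderError("VCF has no samples")
        if "AD" not in vf.header.formats:
            raise MalformedHeaderError("VCF lacks an AD FORMAT field")
        for rec in vf:
            if rec.chrom not in known:
                raise UnknownChromosomeError(f"unknown chromosome {rec.chrom!r} in VCF")
            if rec.alts is None or len(rec.alts) != 1:
                raise MultiallelicRecordError(
                    f"record {rec.chrom}:{rec.pos} is not biallelic"
                )
            if len(rec.ref) != 1 or len(rec.alts[0]) != 1:
                raise FileFormatError(f"record {rec.chrom}:{rec.pos} is not a SNP")
            chroms.append(rec.chrom)
            pos.append(rec.pos)
            ref.append(rec.ref)
            alt.append(rec.alts[0])
            row = []
            for s in samples:
                ad = rec.samples[s].get("AD")
                if ad is None or len(ad) < 2:
                    row.append((0, 0))
                else:
                    row.append((int(ad[0] or 0), int(ad[1] or 0)))
            depth_rows.append(row)
    panel = SnpPanel(
        chroms=np.array(chroms, dtype=object),
        pos=np.array(pos, dtype=np.int64),
        allele_a=np.array(ref, dtype=object),
        allele_b=np.array(alt, dtype=object),
        genome=genome,
    )
    ad_arr = np.array(depth_rows, dtype=np.int32)  # (n_snp, n_sample, 2)
    return panel, ReadCountMatrix(
        depth_a=ad_arr[:, :, 0].T.copy(),
        depth_b=ad_arr[:, :, 1].T.copy(),
        ids=samples,
        mean_depth=mean_depth,
        error_rate=error_rate,
    )


@dataclass
class PipelineConfig:
    """End-to-end pipeline parameters (YAML-serialisable).

    Defaults follow the motivating study design: a 16-chromosome ~12 Mb
    genome, 5,000-SNP panel, ~4× coverage with 0.5% read error, 95%
    detection threshold, 50-SNP smoothing window, and rough cohorts of 92
    (BY backcross) and 88 (3S backcross).
    """

    seed: int = 1
    genome_scale: float = 1.0
    n_snps: int = 5000
    pi_alt: float = 0.2
    mut_carrier_fraction: float = 0.8
    coverage: float = 4.0
    error_rate: float = 0.005
    pool_coverage: float = 200.0
    n_pool: int = 1000
    n_rough_by: int = 92
    n_rough_3s: int = 88
    n_second_gen_rough: int = 39
    n_second_gen_smooth: int = 12
    detect_threshold: float = 0.95
    min_run: int = 5
    smooth_window: int = 50
    control_threshold: float = 0.75
    min_posterior: float = 0.95

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is required (no wall-clock seeding)")
        if not 0 < self.detect_threshold <= 1:
            raise ValueError("detect_threshold must be in (0, 1]")
        if not 0 <= self.pi_alt <= 1:
            raise ValueError("pi_alt must be in [0, 1]")
        if self.min_run < 1 or self.smooth_window < 1:
            raise ValueError("min_run and smooth_window must be >= 1")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise FileFormatError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
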