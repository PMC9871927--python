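"""Readers/writers for the pipeline's exchange formats, plus run configuration.

Internal coordinates are 1-based inclusive everywhere (the VCF/GFF
convention); BED input is 0-based half-open and converted at the boundary.
Readers reject malformed coordinates rather than coercing them, and every
writer's output is re-readable by its paired reader.

TSV tables are tab-delimited with a header row, UTF-8, ``.`` for missing
values.  VCF records are read through :mod:`pysam` and written in a canonical
text form whose FILTER column carries the cascade's label vocabulary.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import pysam
import yaml

from .mutstats import GeneModel, MutationRecord
from .popsim import RegimeConfig
from .seqsim import SeqParams
from .varfilter import FILTER_LABELS, FilterParams

__all__ = [
    "VcfVariant",
    "RunConfig",
    "read_vcf",
    "write_vcf",
    "read_bed",
    "read_gff",
    "write_gff",
    "read_catalogue_tsv",
    "write_catalogue_tsv",
    "read_pileups_vcf",
    "write_pileups_vcf",
    "write_calls_vcf",
    "write_tsv",
    "read_tsv",
]

logger = logging.getLogger("degensim")

_VCF_INFO_DEFS = {
    "DP": ('##INFO=<ID=DP,Number=1,Type=Integer,Description="Total read depth">'),
    "AF": (
        '##INFO=<ID=AF,Number=A,Type=Float,Description="Combined allele frequency per alt">'
    ),
    "DP4": (
        '##INFO=<ID=DP4,Number=4,Type=Integer,'
        'Description="Ref-forward, ref-reverse, alt-forward, alt-reverse read counts">'
    ),
    "SRF": ('##INFO=<ID=SRF,Number=1,Type=Integer,Description="Reference reads, first-forward orientation">'),
    "SRR": ('##INFO=<ID=SRR,Number=1,Type=Integer,Description="Reference reads, first-reverse orientation">'),
    "SAF": ('##INFO=<ID=SAF,Number=A,Type=Integer,Description="Alternate reads per alt, first-forward orientation">'),
    "SAR": ('##INFO=<ID=SAR,Number=A,Type=Integer,Description="Alternate reads per alt, first-reverse orientation">'),
    "MBQ": ('##INFO=<ID=MBQ,Number=1,Type=Float,Description="Mean base quality">'),
}

_FILTER_DESCRIPTIONS = {
    "low_qual": "Site score below the QUAL threshold (criterion A)",
    "no_consensus": "Failed the consensus PASS analogue (criterion B)",
    "low_orientation_af": "AF not above threshold in both read orientations",
    "low_reads": "Insufficient reads per orientation or low base quality",
    "rrna": "Inside an excluded (rRNA) region",
    "starter_background": "Already above threshold in the starter culture",
    "insufficient_recurrence": "Too few subcultures above the recurrence AF",
    "depth_artifact": "Allele frequency tracks sequencing depth",
}


@dataclass
class VcfVariant:
    """One VCF record; multiallelic records are kept intact (one row, n alts)."""

    chrom: str
    pos: int
    ref: str
    alts: tuple[str, ...]
    id: str = "."
    qual: float | None = None
    filters: tuple[str, ...] = ()
    info: dict = field(default_factory=dict)


def read_vcf(
    path: str | Path, required_info: Sequence[str] = ("DP", "AF")
) -> tuple[list[VcfVariant], str]:
    """Read a VCF 4.2 file into :class:`VcfVariant` records plus its header text.

    Positions stay 1-based; multiallelic records are passed through intact
    (splitting is the filter module's job).  Raises ``ValueError`` naming the
    key when a required INFO key is absent, and wraps parse failures with the
    offending record number.
    """
    path = str(path)
    records: list[VcfVariant] = []
    with pysam.VariantFile(path) as vcf:
        header_text = str(vcf.header)
        for n, rec in enumerate(vcf, start=1):
            try:
                info = {}
                for key, value in rec.info.items():
                    info[key] = tuple(value) if isinstance(value, tuple) else value
                for key in required_info:
                    if key not in info:
                        raise ValueError(
                            f"record {n} ({rec.chrom}:{rec.pos}) missing required INFO key {key!r}"
                        )
                records.append(
                    VcfVariant(
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref=rec.ref,
                        alts=tuple(rec.alts or ()),
                        id=rec.id or ".",
                        qual=rec.qual,
                        filters=tuple(rec.filter.keys()),
                        info=info,
                    )
                )
            except ValueError:
                raise
            except Exception as exc:  # pragma: no cover - defensive
                raise ValueError(f"malformed VCF record {n} in {path}: {exc}") from exc
    return records, header_text


def _fmt_info_value(value) -> str:
    if isinstance(value, bool):
        return ""
    if isinstance(value, tuple):
        return ",".join(_fmt_info_value(v) for v in value)
    if isinstance(value, float):
        return f"{value:.6g}"
    return str(value)


def _minimal_header(contigs: Iterable[tuple[str, int]]) -> str:
    # the explicit PASS definition matches pysam's header normalization,
    # keeping write->read->write byte-stable
    lines = [
        "##fileformat=VCFv4.2",
        '##FILTER=<ID=PASS,Description="All filters passed">',
    ]
    lines += [f"##contig=<ID={c},length={ln}>" for c, ln in contigs]
    lines += list(_VCF_INFO_DEFS.values())
    lines += [
        f'##FILTER=<ID={label},Description="{_FILTER_DESCRIPTIONS[label]}">'
        for label in sorted(FILTER_LABELS)
    ]
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    return "\n".join(lines) + "\n"


def write_vcf(
    path: str | Path,
    records: Sequence[VcfVariant],
    header_text: str | None = None,
    contig_lengths: dict[str, int] | None = None,
) -> None:
    """Write records as VCF 4.2 text (canonical formatting, re-readable).

    When ``header_text`` (e.g. from :func:`read_vcf`) is omitted, a minimal
    header with the pipeline's INFO/FILTER vocabulary is generated.
    """
    if header_text is None:
        if contig_lengths is None:
            contig_lengths = {}
            for r in records:
                contig_lengths[r.chrom] = max(
                    contig_lengths.get(r.chrom, 0), r.pos + len(r.ref) + 1000
                )
        header_text = _minimal_header(sorted(contig_lengths.items()))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(header_text)
        for r in records:
            info = ";".join(
                key if isinstance(value, bool) and value else f"{key}={_fmt_info_value(value)}"
                for key, value in r.info.items()
            )
            qual = "." if r.qual is None else f"{r.qual:.6g}"
            filt = ";".join(r.filters) if r.filters else "PASS"
            fh.write(
                f"{r.chrom}\t{r.pos}\t{r.id}\t{r.ref}\t{','.join(r.alts)}\t"
                f"{qual}\t{filt}\t{info or '.'}\n"
            )


def write_calls_vcf(path: str | Path, calls: pd.DataFrame) -> None:
    """Export a cascade ``calls`` table as VCF with labels in FILTER."""
    records = []
    for row in calls.itertuples():
        filters = tuple(row.labels.split(",")) if row.labels else ()
        records.append(
            VcfVariant(
                chrom=row.chrom,
                pos=int(row.pos),
                ref=row.ref,
                alts=(row.alt,),
                qual=float(row.qual),
                filters=filters,
                info={
                    "DP": int(row.fwd_ref + row.fwd_alt + row.rev_ref + row.rev_alt),
                    "AF": (float(row.af),),
                    "DP4": (
                        int(row.fwd_ref),
                        int(row.rev_ref),
                        int(row.fwd_alt),
                        int(row.rev_alt),
                    ),
                },
            )
        )
    write_vcf(path, records)


def write_pileups_vcf(path: str | Path, pileups: pd.DataFrame) -> None:
    """Write a seqsim-dialect pileup table as VCF with orientation-count INFO keys.

    Rows sharing (chrom, pos, ref, subculture, replicate) are emitted as one
    (possibly multiallelic) record with Number=A alt counts; the subculture
    and replicate ride in the ID column as ``replicate:subculture:pos``.
    """
    records = []
    keys = ["chrom", "pos", "ref", "subculture", "replicate"]
    for (chrom, pos, ref, sub, rep), grp in pileups.groupby(keys, sort=True):
        depth = int(
            grp[["fwd_ref", "fwd_alt", "rev_ref", "rev_alt"]].to_numpy().sum()
        )
        alts = tuple(grp["alt"])
        alt_depth = (grp["fwd_alt"] + grp["rev_alt"]).to_numpy()
        records.append(
            VcfVariant(
                chrom=chrom,
                pos=int(pos),
                ref=ref,
                alts=alts,
                id=f"{rep}:{int(sub)}:{int(pos)}",
                info={
                    "DP": depth,
                    "AF": tuple(float(a) / depth if depth else 0.0 for a in alt_depth),
                    "SRF": int(grp["fwd_ref"].iloc[0]),
                    "SRR": int(grp["rev_ref"].iloc[0]),
                    "SAF": tuple(int(v) for v in grp["fwd_alt"]),
                    "SAR": tuple(int(v) for v in grp["rev_alt"]),
                    "MBQ": float(grp["mean_bq"].mean()),
                },
            )
        )
    write_vcf(path, records)


def read_pileups_vcf(path: str | Path) -> pd.DataFrame:
    """Read a pileup VCF written by :func:`write_pileups_vcf` back into the
    seqsim dialect, splitting multiallelic records into biallelic rows."""
    from .varfilter import MultiallelicPileup, split_multiallelic

    records, _ = read_vcf(
        path, required_info=("DP", "AF", "SRF", "SRR", "SAF", "SAR", "MBQ")
    )
    rows = []
    for rec in records:
        try:
            rep, sub, _ = rec.id.split(":")
        except ValueError as exc:
            raise ValueError(
                f"pileup VCF record at {rec.chrom}:{rec.pos} lacks the "
                "replicate:subculture:pos ID convention"
            ) from exc
        saf = rec.info["SAF"] if isinstance(rec.info["SAF"], tuple) else (rec.info["SAF"],)
        sar = rec.info["SAR"] if isinstance(rec.info["SAR"], tuple) else (rec.info["SAR"],)
        multi = MultiallelicPileup(
            chrom=rec.chrom,
            pos=rec.pos,
            ref=rec.ref,
            alts=rec.alts,
            fwd_ref=int(rec.info["SRF"]),
            rev_ref=int(rec.info["SRR"]),
            fwd_alts=tuple(int(v) for v in saf),
            rev_alts=tuple(int(v) for v in sar),
            mean_bq=float(rec.info["MBQ"]),
            subculture=int(sub),
            replicate=rep,
        )
        for call in split_multiallelic(multi):
            rows.append(
                dict(
                    chrom=call.chrom, pos=call.pos, ref=call.ref, alt=call.alt,
                    fwd_ref=call.fwd_ref, fwd_alt=call.fwd_alt,
                    rev_ref=call.rev_ref, rev_alt=call.rev_alt,
                    mean_bq=call.mean_bq,
                    subculture=call.subculture, replicate=call.replicate,
                )
            )
    columns = [
        "chrom", "pos", "ref", "alt", "fwd_ref", "fwd_alt", "rev_ref", "rev_alt",
        "mean_bq", "subculture", "replicate",
    ]
    return pd.DataFrame(rows, columns=columns)


def read_bed(path: str | Path) -> list[tuple[str, int, int]]:
    """Read a 3+ column BED into merged 1-based inclusive intervals.

    BED's 0-based half-open ``(start, end)`` becomes ``[start + 1, end]``;
    overlapping or adjacent intervals on a chromosome are merged.  Raises on
    ``start >= end`` with the line number.
    """
    intervals: list[tuple[str, int, int]] = []
    with open(path, encoding="utf-8") as fh:
        for n, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{n}: BED needs >= 3 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{n}: non-integer BED coordinates") from exc
            if start < 0 or start >= end:
                raise ValueError(f"{path}:{n}: invalid BED interval {start}..{end}")
            intervals.append((fields[0], start + 1, end))
    intervals.sort()
    merged: list[tuple[str, int, int]] = []
    for chrom, s, e in intervals:
        if merged and merged[-1][0] == chrom and s <= merged[-1][2] + 1:
            merged[-1] = (chrom, merged[-1][1], max(merged[-1][2], e))
        else:
            merged.append((chrom, s, e))
    return merged


def read_gff(path: str | Path, feature_types: Sequence[str] = ("gene",)) -> list[GeneModel]:
    """Read gene features from GFF3 into :class:`GeneModel` records.

    Coordinates are kept 1-based inclusive as-is; ``gene_id`` comes from the
    ``ID`` attribute (error listing the line if absent).  Features of other
    types are skipped with a logged count.
    """
    genes: list[GeneModel] = []
    skipped = 0
    with open(path, encoding="utf-8") as fh:
        for n, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}:{n}: GFF3 needs 9 tab-separated columns")
            if fields[2] not in feature_types:
                skipped += 1
                continue
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise ValueError(f"{path}:{n}: non-integer GFF coordinates") from exc
            attrs = dict(
                kv.split("=", 1) for kv in fields[8].split(";") if "=" in kv
            )
            if "ID" not in attrs:
                raise ValueError(f"{path}:{n}: gene feature missing ID attribute: {line}")
            genes.append(
                GeneModel(
                    gene_id=attrs["ID"],
                    chrom=fields[0],
                    start=start,
                    end=end,
                    strand=fields[6],
                    product=attrs.get("product", ""),
                )
            )
    if skipped:
        logger.info("read_gff: skipped %d non-gene feature(s)", skipped)
    return genes


def write_gff(path: str | Path, genes: Sequence[GeneModel]) -> None:
    """Write gene models as GFF3 (round-trips through :func:`read_gff`)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.gene_id}"
            if g.product:
                attrs += f";product={g.product}"
            fh.write(
                f"{g.chrom}\tdegensim\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )


_CATALOGUE_COLUMNS = ["isolate_id", "chrom", "pos", "ref", "alt", "kind", "gene_id"]


def write_catalogue_tsv(path: str | Path, catalogue: Sequence[MutationRecord]) -> None:
    """Write a mutation catalogue as TSV (``.`` for missing gene ids)."""
    df = pd.DataFrame(
        [
            {
                "isolate_id": m.isolate_id,
                "chrom": m.chrom,
                "pos": m.pos,
                "ref": m.ref,
                "alt": m.alt,
                "kind": m.kind,
                "gene_id": m.gene_id or ".",
            }
            for m in catalogue
        ],
        columns=_CATALOGUE_COLUMNS,
    )
    write_tsv(path, df)


def read_catalogue_tsv(path: str | Path) -> list[MutationRecord]:
    """Read a mutation catalogue TSV written by :func:`write_catalogue_tsv`."""
    df = read_tsv(path)
    missing = set(_CATALOGUE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: catalogue TSV missing column(s) {sorted(missing)}")
    return [
        MutationRecord(
            chrom=str(row.chrom),
            pos=int(row.pos),
            ref=str(row.ref),
            alt=str(row.alt),
            kind=str(row.kind),
            isolate_id=str(row.isolate_id),
            gene_id=None if pd.isna(row.gene_id) else str(row.gene_id),
        )
        for row in df.itertuples()
    ]


def write_tsv(path: str | Path, df: pd.DataFrame, index: bool = False) -> None:
    """Tab-delimited, UTF-8, header row, ``.`` for missing values."""
    df.to_csv(path, sep="\t", index=index, na_rep=".", encoding="utf-8")


def read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["."], encoding="utf-8", **kwargs)


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run; fully serializable.

    A manifest echoing the resolved configuration (including the seed) is
    written alongside every run so results can be reproduced exactly.
    """

    seed: int = 0
    regime: RegimeConfig = field(default_factory=RegimeConfig)
    seq: SeqParams = field(default_factory=SeqParams)
    filter: FilterParams = field(default_factory=FilterParams)
    outdir: str = "degensim_run"
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path, overrides: dict | None = None) -> "RunConfig":
        """Load a YAML config; flat ``overrides`` (e.g. CLI flags) win."""
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw, overrides)

    @classmethod
    def from_dict(cls, raw: dict, overrides: dict | None = None) -> "RunConfig":
        raw = dict(raw)
        for key, value in (overrides or {}).items():
            if value is None:
                continue
            if "." in key:
                section, subkey = key.split(".", 1)
                raw.setdefault(section, {})[subkey] = value
            else:
                raw[key] = value
        return cls(
            seed=int(raw.get("seed", 0)),
            regime=RegimeConfig(**raw.get("regime", {})),
            seq=SeqParams(**raw.get("seq", {})),
            filter=FilterParams(**raw.get("filter", {})),
            outdir=str(raw.get("outdir", "degensim_run")),
            log_level=str(raw.get("log_level", "INFO")),
        )

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "regime": dataclasses.asdict(self.regime),
            "seq": dataclasses.asdict(self.seq),
            "filter": dataclasses.asdict(self.filter),
            "outdir": self.outdir,
            "log_level": self.log_level,
        }

    def write_manifest(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")
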