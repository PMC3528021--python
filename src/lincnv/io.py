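"""Readers and writers for the pipeline's on-disk formats.

Disk conventions: probe signal tables carry 1-based positions, SEG call
tables 1-based inclusive coordinates, BED and Circos files 0-based
half-open.  In memory everything is 0-based half-open.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Mapping, Sequence, Tuple

import pandas as pd

from .annotation import AnnotationTrack, Interval
from .genome import GenomeModel
from .segmentation import CNVCall
from .simulate import PlantedEvent, TruthSet

PROBE_HEADER = ["Name", "Chr", "Position", "LRR", "BAF", "GType", "GC"]


class FormatError(ValueError):
    """Raised when an input file does not match its expected format."""


# ---------------------------------------------------------------- probe TSV

def write_probe_signals(df: pd.DataFrame, path) -> None:
    out = pd.DataFrame(
        {
            "Name": df["name"],
            "Chr": df["chrom"],
            "Position": df["pos"] + 1,  # 1-based on disk
            "LRR": df["lrr"],
            "BAF": df["baf"],
            "GType": df["genotype"],
            "GC": df.get("gc", pd.Series([""] * len(df))),
        }
    )
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_probe_signals(path) -> pd.DataFrame:
    try:
        raw = pd.read_csv(path, sep="\t", dtype={"Chr": str, "GType": str})
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"{path}: cannot parse probe signal table: {exc}") from exc
    missing = [c for c in PROBE_HEADER[:6] if c not in raw.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    pos = pd.to_numeric(raw["Position"], errors="coerce")
    lrr = pd.to_numeric(raw["LRR"], errors="coerce")
    baf = pd.to_numeric(raw["BAF"], errors="coerce")
    bad = raw.index[pos.isna() | lrr.isna() | baf.isna()]
    if len(bad):
        raise FormatError(f"{path}: unparseable record at line {int(bad[0]) + 2}")
    df = pd.DataFrame(
        {
            "name": raw["Name"],
            "chrom": raw["Chr"],
            "pos": pos.astype(int) - 1,
            "lrr": lrr.astype(float),
            "baf": baf.astype(float),
            "genotype": raw["GType"],
        }
    )
    if "GC" in raw.columns and not raw["GC"].isna().all():
        df["gc"] = raw["GC"].astype(float)
    return df


# --------------------------------------------------------------------- BED

def write_bed(track: AnnotationTrack, path) -> None:
    with open(path, "w") as fh:
        for iv in track:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.gene_id}\t{iv.biotype}\n")


def read_bed(path, name: str | None = None) -> AnnotationTrack:
    intervals: List[Interval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise FormatError(f"{path}:{lineno}: need >= 4 BED columns")
            try:
                intervals.append(
                    Interval(
                        fields[0],
                        int(fields[1]),
                        int(fields[2]),
                        fields[3],
                        fields[4] if len(fields) > 4 else ".",
                    )
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return AnnotationTrack(name or Path(path).stem, intervals)


# --------------------------------------------------------------------- GTF

def read_gtf(path, name: str | None = None) -> AnnotationTrack:
    """Gene-level track from a GTF: per gene_id, footprint = min start to
    max end over its records.  GTF is 1-based inclusive; converted on read."""
    spans: Dict[str, List] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise FormatError(f"{path}:{lineno}: need 9 GTF columns")
            chrom, start, end, attrs = fields[0], fields[3], fields[4], fields[8]
            info = {}
            for item in attrs.strip().split(";"):
                item = item.strip()
                if not item:
                    continue
                key, _, value = item.partition(" ")
                info[key] = value.strip().strip('"')
            gene_id = info.get("gene_id")
            if gene_id is None:
                raise FormatError(f"{path}:{lineno}: record lacks gene_id")
            s, e = int(start) - 1, int(end)
            biotype = info.get("gene_biotype", info.get("gene_type", "."))
            if gene_id in spans:
                rec = spans[gene_id]
                if rec[0] != chrom:
                    raise FormatError(f"{path}:{lineno}: gene {gene_id} spans chromosomes")
                rec[1] = min(rec[1], s)
                rec[2] = max(rec[2], e)
            else:
                spans[gene_id] = [chrom, s, e, biotype]
    intervals = [
        Interval(chrom, s, e, gid, biotype)
        for gid, (chrom, s, e, biotype) in spans.items()
    ]
    return AnnotationTrack(name or Path(path).stem, intervals)


# --------------------------------------------------------------------- SEG

SEG_COLUMNS = [
    "sample", "chrom", "start", "end", "n_probes", "mean_lrr",
    "mean_dev", "event_class", "loh",
]


def write_calls(calls: Sequence[CNVCall], path) -> None:
    rows = []
    for c in calls:
        rows.append(
            {
                "sample": c.sample,
                "chrom": c.chrom,
                "start": c.start + 1,   # 1-based inclusive on disk
                "end": c.end,
                "n_probes": c.n_probes,
                "mean_lrr": c.mean_lrr,
                "mean_dev": c.mean_dev,
                "event_class": c.event_class,
                "loh": int(c.loh),
            }
        )
    pd.DataFrame(rows, columns=SEG_COLUMNS).to_csv(
        path, sep="\t", index=False, float_format="%.6g"
    )


def read_calls(path) -> List[CNVCall]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in SEG_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    calls = []
    for row in df.itertuples():
        calls.append(
            CNVCall(
                chrom=row.chrom,
                start=int(row.start) - 1,
                end=int(row.end),
                n_probes=int(row.n_probes),
                mean_lrr=float(row.mean_lrr),
                mean_dev=float(row.mean_dev),
                event_class=row.event_class,
                sample="" if pd.isna(row.sample) else str(row.sample),
                loh=bool(row.loh),
            )
        )
    return calls


# ------------------------------------------------------------------- truth

def write_truth(truth: TruthSet, path) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tpurity\tchrom\tstart\tend\tcn_total\tcn_b\tevent_class\tlincrna_genes\n")
        for sample in truth.samples:
            for ev in truth.events[sample]:
                genes = ",".join(ev.lincrna_genes)
                fh.write(
                    f"{sample}\t{truth.purity[sample]:.6g}\t{ev.chrom}\t{ev.start}\t"
                    f"{ev.end}\t{ev.cn_total}\t{ev.cn_b}\t{ev.event_class}\t{genes}\n"
                )


def read_truth(path) -> TruthSet:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "lincrna_genes": str})
    events: Dict[str, List[PlantedEvent]] = {}
    purity: Dict[str, float] = {}
    for row in df.itertuples():
        genes = ()
        if isinstance(row.lincrna_genes, str) and row.lincrna_genes:
            genes = tuple(row.lincrna_genes.split(","))
        events.setdefault(row.sample, []).append(
            PlantedEvent(
                row.chrom, int(row.start), int(row.end),
                int(row.cn_total), int(row.cn_b), row.event_class, genes,
            )
        )
        purity[row.sample] = float(row.purity)
    return TruthSet(
        events={s: tuple(v) for s, v in events.items()}, purity=purity
    )


# ------------------------------------------------------------------ genome

def write_genome(genome: GenomeModel, path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tlength\n")
        for chrom, length in genome.chromosomes.items():
            fh.write(f"{chrom}\t{length}\n")


def read_genome(path, female: bool = True) -> GenomeModel:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return GenomeModel(dict(zip(df["chrom"], df["length"].astype(int))), female=female)


# ------------------------------------------------------------------ circos

def write_circos(freqs: pd.DataFrame, column: str, path) -> None:
    """One ``chrom start end value`` line per bin for one direction."""
    with open(path, "w") as fh:
        for row in freqs.itertuples():
            fh.write(f"{row.chrom} {row.start} {row.end} {getattr(row, column):.6g}\n")


def read_circos(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.split()
            if len(fields) != 4:
                raise FormatError(f"{path}:{lineno}: need 4 whitespace fields")
            rows.append((fields[0], int(fields[1]), int(fields[2]), float(fields[3])))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])


# ---------------------------------------------------------------- Ct table

CT_COLUMNS = ["sample", "assay", "role", "input_ng", "replicate", "ct"]


def write_ct_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.8g")


def read_ct_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in CT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    return df


# ---------------------------------------------------------------- manifest

def write_manifest(manifest: Mapping, path) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_manifest(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
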