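"""Readers and writers for the on-disk interchange formats.

TSV is the canonical format (first column gene id, header = sample ids);
GCT 1.2 and GMT are supported because they are the community standards the
real data would arrive in.  Writers prepend a ``#`` header comment carrying
the tool version and an optional config hash; readers skip such comments.
"""

from __future__ import annotations

import csv
import warnings

import numpy as np
import pandas as pd

from . import __version__
from .enrichment import GeneSetCollection
from .synthdata import ClinicalCohortSet


def _header_comment(config_hash: str | None = None) -> str:
    tag = f";config_hash={config_hash}" if config_hash else ""
    return f"# radbench v{__version__}{tag}\n"


def write_expression(expr: pd.DataFrame, path, format: str = "tsv",
                     config_hash: str | None = None) -> None:
    if format == "tsv":
        with open(path, "w") as fh:
            fh.write(_header_comment(config_hash))
            fh.write("gene_id\t" + "\t".join(map(str, expr.columns)) + "\n")
            for gid, row in zip(expr.index, expr.to_numpy()):
                fh.write(str(gid) + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")
    elif format == "gct":
        with open(path, "w") as fh:
            fh.write("#1.2\n")
            fh.write(f"{expr.shape[0]}\t{expr.shape[1]}\n")
            fh.write("Name\tDescription\t" + "\t".join(map(str, expr.columns)) + "\n")
            for gid, row in zip(expr.index, expr.to_numpy()):
                fh.write(f"{gid}\tna\t" + "\t".join(repr(float(v)) for v in row) + "\n")
    else:
        raise ValueError(f"unknown expression format: {format}")


def read_expression(path, format: str = "tsv") -> pd.DataFrame:
    if format == "tsv":
        return _read_expression_tsv(path)
    if format == "gct":
        return _read_expression_gct(path)
    raise ValueError(f"unknown expression format: {format}")


def _read_expression_tsv(path) -> pd.DataFrame:
    with open(path) as fh:
        lines = [(i + 1, ln.rstrip("\n")) for i, ln in enumerate(fh)]
    lines = [(no, ln) for no, ln in lines if ln and not ln.startswith("#")]
    if not lines:
        raise ValueError(f"{path}: no data")
    header = lines[0][1].split("\t")
    samples = header[1:]
    genes, data, seen = [], [], {}
    for no, ln in lines[1:]:
        fields = ln.split("\t")
        if len(fields) != len(header):
            raise ValueError(
                f"{path}:{no}: expected {len(header)} columns, got {len(fields)}")
        gid = fields[0]
        if gid in seen:
            raise ValueError(
                f"{path}:{no}: duplicate gene id {gid!r} "
                f"(first seen at line {seen[gid]})")
        seen[gid] = no
        row = []
        for ci, val in enumerate(fields[1:], start=2):
            if val == "":
                raise ValueError(f"{path}:{no}: missing cell at column {ci}")
            row.append(float(val))
        genes.append(gid)
        data.append(row)
    return pd.DataFrame(np.asarray(data, dtype=float), index=genes,
                        columns=samples)


def _read_expression_gct(path) -> pd.DataFrame:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if not lines or not lines[0].startswith("#1.2"):
        raise ValueError(f"{path}:1: not a GCT 1.2 file (missing '#1.2')")
    try:
        nrows, ncols = (int(x) for x in lines[1].split("\t")[:2])
    except (IndexError, ValueError) as exc:
        raise ValueError(f"{path}:2: malformed dims line") from exc
    header = lines[2].split("\t")
    if len(header) != ncols + 2:
        raise ValueError(
            f"{path}:3: expected {ncols + 2} header fields, got {len(header)}")
    body = [ln for ln in lines[3:] if ln]
    if len(body) != nrows:
        raise ValueError(
            f"{path}: dims line declares {nrows} rows, found {len(body)}")
    genes, data, seen = [], [], set()
    for off, ln in enumerate(body, start=4):
        fields = ln.split("\t")
        if len(fields) != ncols + 2:
            raise ValueError(
                f"{path}:{off}: expected {ncols + 2} fields, got {len(fields)}")
        if fields[0] in seen:
            raise ValueError(f"{path}:{off}: duplicate gene id {fields[0]!r}")
        seen.add(fields[0])
        genes.append(fields[0])
        data.append([float(v) for v in fields[2:]])
    return pd.DataFrame(np.asarray(data, dtype=float), index=genes,
                        columns=header[2:])


def write_clinical(cohorts: ClinicalCohortSet, path,
                   config_hash: str | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_header_comment(config_hash))
        cols = ["sample_id", "cohort_id", "outcome_type", "time", "event", "rt"]
        writer = csv.writer(fh)
        writer.writerow(cols)
        for sid, row in cohorts.clinical.iterrows():
            writer.writerow([sid, row["cohort_id"], row["outcome_type"],
                             repr(float(row["time"])), int(row["event"]),
                             int(row["rt"])])


def read_clinical(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    required = {"sample_id", "cohort_id", "outcome_type", "time", "event", "rt"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing clinical columns: {sorted(missing)}")
    return df.set_index("sample_id")


def write_probes(arrays, inten_path, map_path,
                 config_hash: str | None = None) -> None:
    write_expression(arrays.intensities.rename_axis("probe_id"),
                     inten_path, config_hash=config_hash)
    with open(map_path, "w") as fh:
        fh.write(_header_comment(config_hash))
        fh.write("probe_id\tgene_id\n")
        for pid, gid in arrays.probe_to_gene.items():
            fh.write(f"{pid}\t{gid}\n")


def read_probe_map(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", comment="#")
    if not {"probe_id", "gene_id"} <= set(df.columns):
        raise ValueError(f"{path}: need probe_id and gene_id columns")
    return df.set_index("probe_id")["gene_id"]


def write_scores(scores: pd.Series, path, config_hash: str | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_header_comment(config_hash))
        fh.write("sample_id\tscore\n")
        for sid, v in scores.items():
            fh.write(f"{sid}\t{float(v)!r}\n")


def read_scores(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", comment="#")
    return df.set_index("sample_id")["score"].astype(float)


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT gene-set file (set name, description, members...)."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for no, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                warnings.warn(f"{path}:{no}: set {fields[0]!r} has no members; "
                              "dropped")
                continue
            name = fields[0]
            if name in sets:
                raise ValueError(f"{path}:{no}: duplicate set name {name!r}")
            members = [g for g in fields[2:] if g]
            dedup = list(dict.fromkeys(members))
            if len(dedup) < len(members):
                warnings.warn(f"{path}:{no}: duplicate members in {name!r} "
                              "deduplicated")
            if not dedup:
                warnings.warn(f"{path}:{no}: set {name!r} empty; dropped")
                continue
            sets[name] = dedup
    universe = list(dict.fromkeys(g for mem in sets.values() for g in mem))
    return GeneSetCollection(sets=sets, universe=universe)


def write_gmt(collection: GeneSetCollection, path,
              description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, members in collection.sets.items():
            fh.write("\t".join([name, description] + list(members)) + "\n")
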