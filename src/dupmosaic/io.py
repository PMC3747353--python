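"""Readers and writers for the package's interchange formats.

All genomic output is 0-based half-open (BED convention).  Every writer
has a matching reader and round-trips with field equality.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

from .matrix import AlignmentMatrix
from .mosaic import DupliconOccurrence, GenomicInterval
from .permutation import DupliconCall

__all__ = [
    "RunConfig",
    "read_config",
    "write_runs_tsv",
    "read_runs_tsv",
    "write_calls_bed",
    "read_calls_bed",
    "write_occurrences_tsv",
    "read_occurrences_tsv",
    "read_bed",
    "write_bed",
    "read_chrom_sizes",
    "read_fasta",
    "write_profiles_tsv",
    "read_profiles_tsv",
]


@dataclass
class RunConfig:
    """All tunable constants of the pipeline in one place.

    Defaults are the framework's published operating point: B = 100
    artificial matrices at alpha = 0.01, duplicon runs of >= 100
    columns, profile thresholds of 95% identity / 100 bp / 10
    duplicons, 25% flanking windows at >90% similarity, and >67%
    clade sharing for core duplicons.
    """

    L: float = 4651.0
    P_o: float = 0.05
    min_len: int = 100
    B: int = 100
    alpha: float = 0.01
    min_identity: float = 0.0
    min_duplicons: int = 10
    profile_min_identity: float = 95.0
    profile_min_len: int = 100
    end_frac: float = 0.25
    min_sim: float = 90.0
    share_threshold: float = 0.67
    seed: int = 0


def read_config(path) -> RunConfig:
    """Flat key = value config file; unknown keys are rejected."""
    cfg = RunConfig()
    ftypes = {f.name: f.type for f in fields(RunConfig)}
    casts = {"float": float, "int": int}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.split("#")[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}: line {lineno}: expected key = value")
            key, val = (tok.strip() for tok in line.split("=", 1))
            if key not in ftypes:
                raise ValueError(f"{path}: line {lineno}: unknown key {key!r}")
            setattr(cfg, key, casts[ftypes[key]](val))
    return cfg


def write_runs_tsv(matrix: AlignmentMatrix, path) -> None:
    """Serialize the matrix as one line per 1-run."""
    with open(path, "w") as fh:
        fh.write(f"#cnv_id={matrix.cnv_id}\tn_cols={matrix.n_cols}\n")
        fh.write("#cnv_id\tsd_id\tstart\tend\n")
        for sd_id, runs in zip(matrix.row_ids, matrix.rows):
            if not runs:
                fh.write(f"{matrix.cnv_id}\t{sd_id}\t.\t.\n")
            for s, e in runs:
                fh.write(f"{matrix.cnv_id}\t{sd_id}\t{s}\t{e}\n")


def read_runs_tsv(path) -> AlignmentMatrix:
    cnv_id, n_cols = None, None
    rows: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#cnv_id="):
                head = dict(tok.split("=", 1) for tok in line[1:].split("\t"))
                cnv_id, n_cols = head["cnv_id"], int(head["n_cols"])
                continue
            if not line or line.startswith("#"):
                continue
            _, sd_id, s, e = line.split("\t")
            rows.setdefault(sd_id, [])
            if s != ".":
                rows[sd_id].append((int(s), int(e)))
    if cnv_id is None:
        raise ValueError(f"{path}: missing #cnv_id header")
    mat = AlignmentMatrix(
        cnv_id=cnv_id,
        n_cols=n_cols,
        row_ids=list(rows),
        rows=[sorted(r) for r in rows.values()],
    )
    mat.validate()
    return mat


_CALLS_HEADER = "#chrom\tstart\tend\tname\tscore\tstrand\tp_value\tstate_label\tcopy_number\tsignificant"


def write_calls_bed(calls, path) -> None:
    """BED6+ duplicon calls: score is the rounded copy number; the
    exact copy number, P value, state label and significance flag
    follow as extra columns so the file round-trips losslessly."""
    rows = sorted(calls, key=lambda c: (c.cnv_id, c.start))
    with open(path, "w") as fh:
        fh.write(_CALLS_HEADER + "\n")
        for i, c in enumerate(rows):
            name = f"{c.cnv_id}:{c.start}-{c.end}"
            fh.write(
                f"{c.cnv_id}\t{c.start}\t{c.end}\t{name}\t{round(c.copy_number)}\t.\t"
                f"{c.p_value:.10g}\t{c.state_label}\t{c.copy_number:.10g}\t"
                f"{int(c.significant)}\n"
            )


def read_calls_bed(path) -> list[DupliconCall]:
    calls = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            calls.append(
                DupliconCall(
                    cnv_id=f[0],
                    start=int(f[1]),
                    end=int(f[2]),
                    state_label=f[7],
                    copy_number=float(f[8]),
                    p_value=float(f[6]),
                    significant=bool(int(f[9])),
                )
            )
    return calls


def write_occurrences_tsv(occurrences, path) -> None:
    with open(path, "w") as fh:
        fh.write("#duplicon_id\tchrom\tstart\tend\tidentity\tlength\n")
        for occ in occurrences:
            iv = occ.interval
            fh.write(
                f"{occ.duplicon_id}\t{iv.chrom}\t{iv.start}\t{iv.end}\t"
                f"{occ.identity:.10g}\t{occ.length}\n"
            )


def read_occurrences_tsv(path) -> list[DupliconOccurrence]:
    occs = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            dup, chrom, s, e, ident, ln = line.rstrip("\n").split("\t")
            occs.append(
                DupliconOccurrence(
                    duplicon_id=dup,
                    interval=GenomicInterval(chrom, int(s), int(e), dup),
                    identity=float(ident),
                    length=int(ln),
                )
            )
    return occs


def read_bed(path, category: str = "other") -> list[GenomicInterval]:
    """BED3+name intervals."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 3:
                raise ValueError(f"{path}: line {lineno}: need at least 3 BED columns")
            name = f[3] if len(f) > 3 else f"{f[0]}:{f[1]}-{f[2]}"
            out.append(GenomicInterval(f[0], int(f[1]), int(f[2]), name, category))
    return out


def write_bed(intervals, path) -> None:
    with open(path, "w") as fh:
        for iv in sorted(intervals, key=lambda x: (x.chrom, x.start)):
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\n")


def read_chrom_sizes(path) -> dict[str, int]:
    sizes = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            chrom, size = line.split()[:2]
            sizes[chrom] = int(size)
    return sizes


def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(path, "fasta")}


def write_profiles_tsv(profiles, path) -> None:
    """0/1 matrix: one row per segment, one column per duplicon."""
    with open(path, "w") as fh:
        if not profiles:
            fh.write("segment_id\n")
            return
        index = profiles[0].index
        fh.write("segment_id\t" + "\t".join(index) + "\n")
        for p in sorted(profiles, key=lambda x: x.segment_id):
            fh.write(p.segment_id + "\t" + "\t".join(str(int(b)) for b in p.bits) + "\n")


def read_profiles_tsv(path):
    from .mosaic import PhyloProfile
    import numpy as np

    profiles = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        index = tuple(header[1:])
        for line in fh:
            f = line.rstrip("\n").split("\t")
            profiles.append(
                PhyloProfile(
                    segment_id=f[0],
                    bits=np.array([int(x) for x in f[1:]], dtype=np.int8),
                    index=index,
                )
            )
    return profiles
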