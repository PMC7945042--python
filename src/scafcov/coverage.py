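"""Per-base depth: bedGraph input, projection onto scaffold coordinates,
summaries, and multi-sample abundance tables for binning tools.

Contig depth enters as bedGraph (0-based half-open, as written by bedtools
genomecov with -bga/-split, so zero-depth intervals are explicit). The
scaffold coverage track sums, at every position of the span, the depth of
all contigs whose interval covers that position; reverse-oriented contigs
contribute their depth vector reversed. Positions covered by no contig
(gaps between contigs) carry depth 0 and are included in the mean/variance
over the span. Variances are population variances (divide by n), matching
their plug-in use in the change-point Z-statistic.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import numpy as np
import pandas as pd

from .coordinates import CoordinateMap

PathLike = Union[str, Path]


class CoverageInputError(ValueError):
    """Raised for malformed or inconsistent depth input."""


@dataclass
class CoverageTrack:
    """Summed per-base depth along one scaffold span."""

    scaffold_id: str
    depth: np.ndarray = field(repr=False)

    @property
    def span(self) -> int:
        return int(self.depth.size)

    @property
    def mean(self) -> float:
        return float(self.depth.mean())

    @property
    def variance(self) -> float:
        return float(self.depth.var())

    @property
    def std(self) -> float:
        return float(self.depth.std())


def read_bedgraph(
    source: Union[PathLike, io.TextIOBase],
    lengths: Mapping[str, int],
) -> dict[str, np.ndarray]:
    """Read 4-column bedGraph into dense per-base depth vectors.

    Intervals may arrive unsorted. Positions not covered by any interval
    default to depth 0 with a warning (input produced without -bga).
    Contigs present in ``lengths`` but absent from the stream get all-zero
    vectors.

    Raises
    ------
    CoverageInputError
        On malformed lines, unknown contigs, or intervals running past the
        contig end.
    """
    if isinstance(source, (str, Path)):
        fh = open(source)
        close = True
        name = str(source)
    else:
        fh, close, name = source, False, "<stream>"
    depths = {cid: np.zeros(n, dtype=float) for cid, n in lengths.items()}
    covered = {cid: np.zeros(n, dtype=bool) for cid, n in lengths.items()}
    try:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise CoverageInputError(f"{name}:{lineno}: expected 4 bedGraph columns")
            cid = fields[0]
            if cid not in depths:
                raise CoverageInputError(f"{name}:{lineno}: unknown contig {cid!r}")
            try:
                start, end = int(fields[1]), int(fields[2])
                value = float(fields[3])
            except ValueError:
                raise CoverageInputError(f"{name}:{lineno}: non-numeric interval or depth") from None
            if not 0 <= start < end:
                raise CoverageInputError(f"{name}:{lineno}: bad interval [{start}, {end})")
            if end > lengths[cid]:
                raise CoverageInputError(
                    f"{name}:{lineno}: interval [{start}, {end}) exceeds length "
                    f"{lengths[cid]} of contig {cid!r}"
                )
            if value < 0:
                raise CoverageInputError(f"{name}:{lineno}: negative depth {value}")
            depths[cid][start:end] = value
            covered[cid][start:end] = True
    finally:
        if close:
            fh.close()
    holes = {cid: int((~m).sum()) for cid, m in covered.items() if not m.all()}
    if holes:
        worst = sorted(holes.items(), key=lambda kv: -kv[1])[:3]
        warnings.warn(
            f"{len(holes)} contig(s) with positions uncovered by any bedGraph interval "
            f"(defaulting to depth 0), e.g. {worst}; was genomecov run with -bga?"
        )
    return depths


def write_bedgraph(depths: Mapping[str, np.ndarray], path: PathLike) -> None:
    """Write per-base depth vectors as run-length-encoded bedGraph (-bga style)."""
    with open(path, "w") as fh:
        for cid in sorted(depths):
            vec = np.asarray(depths[cid])
            if vec.size == 0:
                continue
            change = np.flatnonzero(np.diff(vec)) + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [vec.size]])
            for s, e in zip(starts, ends):
                v = vec[s]
                v_repr = int(v) if float(v).is_integer() else v
                fh.write(f"{cid}\t{s}\t{e}\t{v_repr}\n")


def project_coverage(cmap: CoordinateMap, depths: Mapping[str, np.ndarray]) -> CoverageTrack:
    """Sum contig depth vectors onto the scaffold span.

    Raises
    ------
    CoverageInputError
        If a placed contig has no depth vector or its vector length does not
        match the placement.
    """
    span = cmap.span
    track = np.zeros(span, dtype=float)
    for cid, pl in cmap.placements.items():
        if cid not in depths:
            raise CoverageInputError(
                f"scaffold {cmap.scaffold_id!r}: no depth vector for placed contig {cid!r}"
            )
        vec = np.asarray(depths[cid], dtype=float)
        if vec.size != pl.length:
            raise CoverageInputError(
                f"contig {cid!r}: depth vector length {vec.size} != placed length {pl.length}"
            )
        if pl.orientation == "-":
            vec = vec[::-1]
        track[pl.start : pl.end] += vec
    return CoverageTrack(cmap.scaffold_id, track)


def summarize_coverage(track: CoverageTrack) -> tuple[float, float]:
    """Arithmetic mean and population standard deviation over the span."""
    if track.span == 0:
        raise ValueError(f"scaffold {track.scaffold_id!r}: empty coverage track")
    return track.mean, track.std


def multi_sample_abundance(
    cmaps: Sequence[CoordinateMap],
    per_sample_depths: Sequence[Mapping[str, np.ndarray]],
    sample_names: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-scaffold (mean, variance) of depth in every sample.

    Each sample's depth map is projected independently onto the final
    scaffold coordinates. A sample missing every contig of a scaffold
    legitimately lacks that organism: its cell becomes (0, 0) with a
    warning. ``totalAvgDepth`` is the sum of per-sample means, the
    convention MetaBAT2's depth files use.
    """
    if sample_names is None:
        sample_names = [f"sample_{i + 1}" for i in range(len(per_sample_depths))]
    if len(sample_names) != len(per_sample_depths):
        raise ValueError("sample_names and per_sample_depths length mismatch")
    rows = []
    for cmap in cmaps:
        row: dict[str, object] = {
            "contigName": cmap.scaffold_id,
            "contigLen": cmap.span,
        }
        means = []
        for sname, depths in zip(sample_names, per_sample_depths):
            missing = [cid for cid in cmap.placements if cid not in depths]
            if missing:
                if len(missing) == len(cmap.placements):
                    warnings.warn(
                        f"scaffold {cmap.scaffold_id!r} absent from sample {sname!r}; "
                        "reporting zero abundance"
                    )
                    row[f"{sname}.mean"] = 0.0
                    row[f"{sname}.var"] = 0.0
                    means.append(0.0)
                    continue
                raise CoverageInputError(
                    f"sample {sname!r} provides depth for only part of scaffold "
                    f"{cmap.scaffold_id!r} (missing {missing[:3]}...)"
                )
            track = project_coverage(cmap, depths)
            row[f"{sname}.mean"] = track.mean
            row[f"{sname}.var"] = track.variance
            means.append(track.mean)
        row["totalAvgDepth"] = float(sum(means))
        rows.append(row)
    cols = ["contigName", "contigLen", "totalAvgDepth"]
    for sname in sample_names:
        cols += [f"{sname}.mean", f"{sname}.var"]
    return pd.DataFrame(rows, columns=cols)


def write_metabat2(abundance: pd.DataFrame, path: PathLike) -> None:
    """MetaBAT2-style depth table (jgi_summarize layout)."""
    abundance.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_maxbin2(abundance: pd.DataFrame, prefix: PathLike) -> list[Path]:
    """One id<TAB>abundance file per sample, as MaxBin 2.0 expects."""
    prefix = Path(prefix)
    paths = []
    samples = [c[: -len(".mean")] for c in abundance.columns if c.endswith(".mean")]
    for sname in samples:
        p = prefix.parent / f"{prefix.name}.{sname}.abund"
        abundance[["contigName", f"{sname}.mean"]].to_csv(
            p, sep="\t", index=False, header=False, float_format="%.6g"
        )
        paths.append(p)
    return paths


def write_concoct(abundance: pd.DataFrame, path: PathLike) -> None:
    """CONCOCT coverage table: id plus one mean-depth column per sample."""
    samples = [c[: -len(".mean")] for c in abundance.columns if c.endswith(".mean")]
    out = abundance[["contigName"] + [f"{s}.mean" for s in samples]].copy()
    out.columns = ["contig_id"] + [f"cov_mean_{s}" for s in samples]
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_coverage_tracks(tracks: Iterable[CoverageTrack], path: PathLike) -> None:
    """Per-base scaffold coverage, run-length encoded as bedGraph-style TSV."""
    with open(path, "w") as fh:
        fh.write("scaffold_id\tstart\tend\tdepth\n")
        for track in tracks:
            vec = track.depth
            if vec.size == 0:
                continue
            change = np.flatnonzero(np.diff(vec)) + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [vec.size]])
            for s, e in zip(starts, ends):
                v = vec[s]
                v_repr = int(v) if float(v).is_integer() else v
                fh.write(f"{track.scaffold_id}\t{s}\t{e}\t{v_repr}\n")


def write_coverage_summary(tracks: Iterable[CoverageTrack], path: PathLike) -> None:
    """Mean and population standard deviation of coverage per scaffold."""
    with open(path, "w") as fh:
        fh.write("# std is the population standard deviation over the full span,\n")
        fh.write("# gap positions included at depth 0\n")
        fh.write("scaffold_id\tspan\tmean\tstd\n")
        for track in tracks:
            mean, std = summarize_coverage(track)
            fh.write(f"{track.scaffold_id}\t{track.span}\t{mean:.6g}\t{std:.6g}\n")
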