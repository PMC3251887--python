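"""Genome-build registry and array probe grids.

A :class:`GenomeBuild` holds chromosome lengths and p/q arm boundaries in
0-based half-open coordinates.  A bundled hg18-like table (approximate
cytoband-derived boundaries) is the default; users may load their own
config.  Probe grids for the two array platforms are tiled deterministically
per arm: the BAC platform at ~1 Mb spacing, the oligonucleotide platform at
~40 kb spacing.  Centromeric gaps between p_end and q_start carry no probes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "GenomeBuild",
    "ProbeGrid",
    "GenomeConfigError",
    "PLATFORM_SPACING",
    "load_genome_config",
    "default_build",
    "build_probe_grid",
    "assign_arm",
]

#: target inter-probe spacing per platform, in bp
PLATFORM_SPACING = {"BAC": 1_000_000, "OLIGO": 40_000}

CHROMOSOME_LABELS = [str(i) for i in range(1, 23)] + ["X", "Y"]


class GenomeConfigError(ValueError):
    """Raised when a genome config document fails validation."""


@dataclass(frozen=True)
class GenomeBuild:
    """Chromosome lengths and arm intervals for one genome build.

    Attributes
    ----------
    name : str
        Build identifier (e.g. ``"hg18-approx"``).
    chromosomes : tuple of (str, int)
        Ordered ``(label, length_bp)`` pairs, 24 entries (1-22, X, Y).
    arms : dict
        Maps ``(chromosome, arm)`` with ``arm in {"p", "q"}`` to a
        half-open interval ``[start, end)`` in bp.
    """

    name: str
    chromosomes: tuple[tuple[str, int], ...]
    arms: dict[tuple[str, str], tuple[int, int]] = field(hash=False)

    @property
    def chromosome_labels(self) -> list[str]:
        return [label for label, _ in self.chromosomes]

    def length(self, chromosome: str) -> int:
        for label, n in self.chromosomes:
            if label == chromosome:
                return n
        raise KeyError(f"unknown chromosome {chromosome!r}")

    def arm_interval(self, chromosome: str, arm: str) -> tuple[int, int]:
        return self.arms[(chromosome, arm)]


@dataclass(frozen=True)
class ProbeGrid:
    """Ordered probe layout for one array platform.

    ``probes`` is a DataFrame with columns ``probe_id, chrom, start, end``
    sorted in genome order; no probe spans an arm boundary.
    """

    platform: str
    probes: pd.DataFrame = field(hash=False)
    spacing: int

    def __len__(self) -> int:
        return len(self.probes)

    def chromosome_index(self, chromosome: str) -> np.ndarray:
        """Positional indices of the probes on one chromosome."""
        return np.flatnonzero((self.probes["chrom"] == chromosome).to_numpy())

    def to_bed(self, path) -> None:
        """Write the grid as BED (chrom, start, end, probe_id)."""
        bed = self.probes[["chrom", "start", "end", "probe_id"]].copy()
        bed["chrom"] = "chr" + bed["chrom"].astype(str)
        bed.to_csv(path, sep="\t", header=False, index=False)


def _validate_entry(entry: dict) -> None:
    label = entry.get("label", "<missing label>")
    for key in ("label", "length", "p_end", "q_start"):
        if key not in entry:
            raise GenomeConfigError(f"chromosome {label!r}: missing field {key!r}")
    length, p_end, q_start = entry["length"], entry["p_end"], entry["q_start"]
    if length <= 0:
        raise GenomeConfigError(f"chromosome {label!r}: non-positive length {length}")
    if not (0 < p_end <= q_start):
        raise GenomeConfigError(
            f"chromosome {label!r}: arms overlap or are mis-ordered "
            f"(p_end={p_end}, q_start={q_start})"
        )
    if q_start >= length:
        raise GenomeConfigError(
            f"chromosome {label!r}: q arm starts at or beyond chromosome end"
        )


def load_genome_config(source) -> GenomeBuild:
    """Load and validate a genome config document.

    Parameters
    ----------
    source : path, file-like or dict
        JSON document (or already-parsed mapping) with a ``chromosomes``
        list of ``{label, length, p_end, q_start}`` entries.  ``q_end``
        defaults to the chromosome length.  All coordinates are 0-based
        half-open.

    Raises
    ------
    GenomeConfigError
        If a chromosome or arm is missing, arms overlap, a length is
        non-positive, or an arm extends beyond the chromosome end.
    """
    if isinstance(source, dict):
        doc = source
    elif hasattr(source, "read"):
        doc = json.load(source)
    else:
        with open(source) as fh:
            doc = json.load(fh)

    entries = doc.get("chromosomes")
    if not entries:
        raise GenomeConfigError("config lists no chromosomes")

    chromosomes = []
    arms: dict[tuple[str, str], tuple[int, int]] = {}
    for entry in entries:
        _validate_entry(entry)
        label = str(entry["label"])
        length = int(entry["length"])
        q_end = int(entry.get("q_end", length))
        if q_end > length:
            raise GenomeConfigError(
                f"chromosome {label!r}: q arm ends beyond chromosome length"
            )
        chromosomes.append((label, length))
        arms[(label, "p")] = (0, int(entry["p_end"]))
        arms[(label, "q")] = (int(entry["q_start"]), q_end)

    labels = [c[0] for c in chromosomes]
    missing = [c for c in CHROMOSOME_LABELS if c not in labels]
    if missing:
        raise GenomeConfigError(f"missing chromosomes: {', '.join(missing)}")
    return GenomeBuild(name=str(doc.get("name", "custom")), chromosomes=tuple(chromosomes), arms=arms)


def default_build() -> GenomeBuild:
    """The bundled hg18-like build (approximate arm boundaries)."""
    with resources.files("nbprofile.data").joinpath("hg18_arms.json").open() as fh:
        return load_genome_config(fh)


def build_probe_grid(build: GenomeBuild, platform: str) -> ProbeGrid:
    """Tile evenly spaced probes along every chromosome arm.

    Probes are contiguous tiles of width equal to the platform spacing
    (the last tile on an arm is clipped), so no probe crosses an arm
    boundary and the grid is fully determined by the build.
    """
    if platform not in PLATFORM_SPACING:
        raise ValueError(f"unknown platform {platform!r}; expected one of {sorted(PLATFORM_SPACING)}")
    spacing = PLATFORM_SPACING[platform]

    rows: list[tuple[str, str, int, int]] = []
    for label, _length in build.chromosomes:
        for arm in ("p", "q"):
            start, end = build.arms[(label, arm)]
            pos = start
            k = 0
            while pos < end:
                probe_end = min(pos + spacing, end)
                rows.append((f"{platform}_{label}{arm}_{k:05d}", label, pos, probe_end))
                pos = probe_end
                k += 1
    probes = pd.DataFrame(rows, columns=["probe_id", "chrom", "start", "end"])
    return ProbeGrid(platform=platform, probes=probes, spacing=spacing)


def assign_arm(probe: tuple[str, int], build: GenomeBuild) -> tuple[str, str | None]:
    """Assign a probe coordinate to its chromosome arm.

    Returns ``(chromosome, "p"|"q")``, or ``(chromosome, None)`` when the
    coordinate falls in the centromeric gap between the arms.

    Raises
    ------
    ValueError
        If the coordinate is negative or beyond the chromosome end.
    """
    chromosome, pos = probe
    length = build.length(chromosome)
    if not (0 <= pos < length):
        raise ValueError(
            f"position {pos} outside chromosome {chromosome} (length {length})"
        )
    for arm in ("p", "q"):
        start, end = build.arms[(chromosome, arm)]
        if start <= pos < end:
            return (chromosome, arm)
    return (chromosome, None)
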