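"""Microsatellite panel definitions: loading, validation, writing, subsetting.

A panel is an ordered list of mononucleotide-repeat (homopolymer) loci.  Each
locus carries the flanking sequence immediately adjacent to the repeat tract,
so downstream read assignment needs no reference genome: the flanks double as
anchors for locating the tract inside an amplicon read.

Coordinates are 0-based half-open throughout (BED convention), so
``repeat_end - repeat_start == ref_repeat_length`` for a mononucleotide tract.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "LocusDefinition",
    "PanelDefinition",
    "PanelError",
    "load_panel",
    "write_panel",
    "subset_panel",
    "MIN_FLANK_LEN",
]

#: Minimum stored flank length; gives headroom over the default anchor length
#: of 10 used by the repeat caller.
MIN_FLANK_LEN = 15

_TSV_COLUMNS = (
    "locus_id",
    "chrom",
    "repeat_start",
    "repeat_end",
    "repeat_unit",
    "ref_repeat_length",
    "left_flank",
    "right_flank",
    "cancer_type_tags",
)

_VALID_BASES = set("ACGT")


class PanelError(ValueError):
    """Raised for malformed or internally inconsistent panel definitions."""


@dataclass
class LocusDefinition:
    """One mononucleotide microsatellite marker.

    ``left_flank``/``right_flank`` are the reference bases immediately
    adjacent to the repeat tract.  The tract must be maximal: the flank base
    touching the tract may not equal ``repeat_unit``, otherwise the stated
    reference length would be ambiguous.
    """

    locus_id: str
    chrom: str
    repeat_start: int
    repeat_end: int
    repeat_unit: str
    ref_repeat_length: int
    left_flank: str
    right_flank: str
    cancer_type_tags: frozenset[str] = field(default_factory=frozenset)

    def validate(self) -> None:
        lid = self.locus_id
        if not lid:
            raise PanelError("locus with empty locus_id")
        if self.repeat_unit not in _VALID_BASES:
            raise PanelError(
                f"{lid}: repeat_unit {self.repeat_unit!r} is not one of A,C,G,T"
            )
        if self.ref_repeat_length < 5:
            raise PanelError(
                f"{lid}: ref_repeat_length {self.ref_repeat_length} < 5"
            )
        if self.repeat_end - self.repeat_start != self.ref_repeat_length:
            raise PanelError(
                f"{lid}: repeat_end - repeat_start = "
                f"{self.repeat_end - self.repeat_start} does not equal "
                f"ref_repeat_length {self.ref_repeat_length}"
            )
        for name, flank in (("left_flank", self.left_flank),
                            ("right_flank", self.right_flank)):
            if len(flank) < MIN_FLANK_LEN:
                raise PanelError(
                    f"{lid}: {name} shorter than {MIN_FLANK_LEN} nt"
                )
            if not set(flank) <= _VALID_BASES:
                raise PanelError(f"{lid}: {name} contains non-ACGT characters")
        if self.left_flank[-1] == self.repeat_unit:
            raise PanelError(
                f"{lid}: tract not maximal (left_flank ends with repeat unit "
                f"{self.repeat_unit!r})"
            )
        if self.right_flank[0] == self.repeat_unit:
            raise PanelError(
                f"{lid}: tract not maximal (right_flank starts with repeat "
                f"unit {self.repeat_unit!r})"
            )

    @property
    def reference_tract(self) -> str:
        """The reference repeat tract sequence."""
        return self.repeat_unit * self.ref_repeat_length


@dataclass
class PanelDefinition:
    """An ordered, validated collection of microsatellite loci."""

    loci: list[LocusDefinition]
    panel_name: str = "panel"
    version: str = "1"

    def validate(self) -> None:
        if not self.loci:
            raise PanelError("empty panel")
        seen: set[str] = set()
        for locus in self.loci:
            locus.validate()
            if locus.locus_id in seen:
                raise PanelError(f"duplicate locus_id {locus.locus_id!r}")
            seen.add(locus.locus_id)

    def __len__(self) -> int:
        return len(self.loci)

    def __iter__(self):
        return iter(self.loci)

    @property
    def locus_ids(self) -> list[str]:
        return [locus.locus_id for locus in self.loci]

    def get(self, locus_id: str) -> LocusDefinition:
        for locus in self.loci:
            if locus.locus_id == locus_id:
                return locus
        raise KeyError(locus_id)


def load_panel(path: str | Path, format: str = "tsv") -> PanelDefinition:
    """Read and validate a panel definition file.

    Only the TSV dialect carries flank sequences and is therefore loadable;
    BED6 is an export-only format (it has no flank columns).
    """
    path = Path(path)
    if format == "bed":
        raise PanelError(
            "BED6 panel files carry no flank sequences or repeat unit and "
            "cannot be loaded; use the TSV dialect"
        )
    if format != "tsv":
        raise PanelError(f"unknown panel format {format!r}")

    loci: list[LocusDefinition] = []
    panel_name = path.stem
    version = "1"
    with open(path) as fh:
        header: Sequence[str] | None = None
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                stripped = line.lstrip("#").strip()
                if stripped.startswith("panel_name="):
                    panel_name = stripped.split("=", 1)[1]
                elif stripped.startswith("version="):
                    version = stripped.split("=", 1)[1]
                elif stripped.startswith("locus_id"):
                    header = tuple(stripped.split("\t"))
                continue
            if header is None:
                header = _TSV_COLUMNS
            fields = line.split("\t")
            if len(fields) < len(_TSV_COLUMNS) - 1:
                raise PanelError(
                    f"{path}:{lineno}: expected at least "
                    f"{len(_TSV_COLUMNS) - 1} tab-separated columns, got "
                    f"{len(fields)}"
                )
            row = dict(zip(_TSV_COLUMNS, fields))
            try:
                start = int(row["repeat_start"])
                end = int(row["repeat_end"])
                ref_len = int(row["ref_repeat_length"])
            except (ValueError, KeyError) as exc:
                raise PanelError(
                    f"{path}:{lineno}: malformed coordinates ({exc})"
                ) from None
            tags = row.get("cancer_type_tags", "") or ""
            loci.append(
                LocusDefinition(
                    locus_id=row["locus_id"],
                    chrom=row["chrom"],
                    repeat_start=start,
                    repeat_end=end,
                    repeat_unit=row["repeat_unit"],
                    ref_repeat_length=ref_len,
                    left_flank=row["left_flank"],
                    right_flank=row["right_flank"],
                    cancer_type_tags=frozenset(
                        t for t in tags.split(",") if t
                    ),
                )
            )
    panel = PanelDefinition(loci=loci, panel_name=panel_name, version=version)
    panel.validate()
    return panel


def write_panel(panel: PanelDefinition, path: str | Path,
                format: str = "tsv") -> None:
    """Write a panel as TSV (round-trippable) or BED6 (coordinates only)."""
    panel.validate()
    path = Path(path)
    with open(path, "w") as fh:
        if format == "tsv":
            fh.write(f"# panel_name={panel.panel_name}\n")
            fh.write(f"# version={panel.version}\n")
            fh.write("# coordinates are 0-based half-open\n")
            fh.write("# " + "\t".join(_TSV_COLUMNS) + "\n")
            for locus in panel:
                fh.write(
                    "\t".join(
                        [
                            locus.locus_id,
                            locus.chrom,
                            str(locus.repeat_start),
                            str(locus.repeat_end),
                            locus.repeat_unit,
                            str(locus.ref_repeat_length),
                            locus.left_flank,
                            locus.right_flank,
                            ",".join(sorted(locus.cancer_type_tags)),
                        ]
                    )
                    + "\n"
                )
        elif format == "bed":
            for locus in panel:
                fh.write(
                    f"{locus.chrom}\t{locus.repeat_start}\t{locus.repeat_end}"
                    f"\t{locus.locus_id}\t{locus.ref_repeat_length}\t+\n"
                )
        else:
            raise PanelError(f"unknown panel format {format!r}")


def subset_panel(panel: PanelDefinition,
                 locus_ids: Iterable[str]) -> PanelDefinition:
    """Restrict a panel to ``locus_ids``, preserving the original order."""
    wanted = set(locus_ids)
    known = set(panel.locus_ids)
    missing = sorted(wanted - known)
    if missing:
        raise PanelError(f"unknown locus ids: {', '.join(missing)}")
    loci = [replace(locus) for locus in panel if locus.locus_id in wanted]
    sub = PanelDefinition(
        loci=loci,
        panel_name=f"{panel.panel_name}_subset{len(loci)}",
        version=panel.version,
    )
    sub.validate()
    return sub
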