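"""Oligonucleotide assembly, 384-well plate layout, and readout files.

Each library probe is synthesized as two oligonucleotides that anneal
into the dsDNA probe: the 5'-biotinylated forward strand carries a 6 bp
adenine linker (plate-proximal), the 11-20 bp variable region, and a 4 bp
adenine linker; the reverse strand is its exact reverse complement (so a
4 bp thymidine linker sits at its 5' distal end and a 6 bp thymidine
linker proximal to the plate). Biotin immobilizes the probe on a
streptavidin-coated well, one probe per well of a 16 x 24 (A1..P24)
microtiter plate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .core import reverse_complement
from .design import LibraryProbe, ProbeLibrary

__all__ = [
    "FORWARD_5P_LINKER",
    "FORWARD_3P_LINKER",
    "ProbeRecord",
    "PlateLayout",
    "PlateReadout",
    "assemble_oligos",
    "default_controls",
    "build_plate_layout",
    "read_readout",
    "write_readout",
]

FORWARD_5P_LINKER = "AAAAAA"  # plate-proximal, 5'-biotinylated end
FORWARD_3P_LINKER = "AAAA"  # distal end

PLATE_ROWS = "ABCDEFGHIJKLMNOP"  # 16 rows
PLATE_COLS = list(range(1, 25))  # 24 columns
N_WELLS = len(PLATE_ROWS) * len(PLATE_COLS)

PROBE_CLASSES = ("library", "positive_control", "negative_control", "empty")


def assemble_oligos(variable_region: str) -> tuple[str, str]:
    """Forward and reverse oligo for one variable region.

    The forward oligo is linker + region + linker (total region + 10 nt);
    the reverse oligo is its full reverse complement.
    """
    n = len(variable_region)
    if not 11 <= n <= 20:
        raise ValueError(f"variable region of {n} bp outside the 11-20 bp range")
    fwd = FORWARD_5P_LINKER + variable_region + FORWARD_3P_LINKER
    return fwd, reverse_complement(fwd)


def strip_linkers(forward_oligo: str) -> str:
    """Recover the variable region from an assembled forward oligo."""
    if not (
        forward_oligo.startswith(FORWARD_5P_LINKER)
        and forward_oligo.endswith(FORWARD_3P_LINKER)
    ):
        raise ValueError("oligo lacks the expected adenyl linkers")
    return forward_oligo[len(FORWARD_5P_LINKER) : -len(FORWARD_3P_LINKER)]


@dataclass(frozen=True)
class ProbeRecord:
    """One plated probe with its assembled oligonucleotides."""

    probe_id: str
    variable_region: str
    probe_class: str = "library"
    source: str = "loaded"

    def __post_init__(self) -> None:
        if self.probe_class not in PROBE_CLASSES:
            raise ValueError(f"unknown probe class {self.probe_class!r}")

    @property
    def forward_oligo(self) -> str:
        return assemble_oligos(self.variable_region)[0]

    @property
    def reverse_oligo(self) -> str:
        return assemble_oligos(self.variable_region)[1]

    @property
    def biotinylated_forward(self) -> bool:
        return self.probe_class != "empty"


def _synthetic_control_region(index: int, positive: bool) -> str:
    """Deterministic synthetic stand-in control sequences.

    The published control probes are not part of this package; these
    synthetic defaults only fix classes and well usage. Positive controls
    carry a W-box core (a strong, well-characterized element), negative
    controls are low-complexity AT repeats that no specific binder in the
    simulator prefers.
    """
    if positive:
        pads = ["ACTG", "CAGT", "GTAC", "TCGA", "AGCT", "GATG"]
        return "TTGACC" + pads[index % 6] + "TTGACT" + pads[(index + 1) % 6]
    unit = ["ATAT", "TATA", "AATT", "TTAA"][index % 4]
    return unit * 5


def default_controls(n_positive: int = 6, n_negative: int = 26) -> list[ProbeRecord]:
    """The control probe set: 6 positive and 26 negative wells by default."""
    controls = [
        ProbeRecord(f"POS{i + 1:02d}", _synthetic_control_region(i, True),
                    "positive_control", "control")
        for i in range(n_positive)
    ]
    controls += [
        ProbeRecord(f"NEG{i + 1:02d}", _synthetic_control_region(i, False),
                    "negative_control", "control")
        for i in range(n_negative)
    ]
    return controls


def well_name(row: int, col: int) -> str:
    return f"{PLATE_ROWS[row]}{col}"


def all_wells() -> list[str]:
    """All 384 well names in column-major order (A1, B1, ..., P1, A2, ...)."""
    return [well_name(r, c) for c in PLATE_COLS for r in range(len(PLATE_ROWS))]


def sort_wells(wells) -> list[str]:
    """Row-major well order (A1, A2, ... P24) used for reports."""
    return sorted(wells, key=lambda w: (w[0], int(w[1:])))


@dataclass
class PlateLayout:
    """Assignment of probes to the wells of one 384-well plate."""

    wells: dict[str, ProbeRecord] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.wells) > N_WELLS:
            raise ValueError("more than 384 wells assigned")
        ids = [p.probe_id for p in self.wells.values() if p.probe_class != "empty"]
        if len(ids) != len(set(ids)):
            raise ValueError("a probe is placed in two wells")

    def probe_at(self, well: str) -> ProbeRecord | None:
        return self.wells.get(well)

    def wells_by_class(self, probe_class: str) -> list[str]:
        return sort_wells(
            w for w, p in self.wells.items() if p.probe_class == probe_class
        )

    def well_of(self, probe_id: str) -> str:
        for w, p in self.wells.items():
            if p.probe_id == probe_id:
                return w
        raise KeyError(probe_id)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for w in all_wells():
            p = self.wells.get(w)
            rows.append(
                {
                    "well": w,
                    "probe_id": p.probe_id if p else "",
                    "class": p.probe_class if p else "empty",
                    "variable_region": p.variable_region if p else "",
                }
            )
        return pd.DataFrame(rows)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "PlateLayout":
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        wells = {}
        for _, row in df.iterrows():
            if row["class"] == "empty" or not row["probe_id"]:
                continue
            wells[row["well"]] = ProbeRecord(
                row["probe_id"], row["variable_region"], row["class"]
            )
        return cls(wells=wells)


def build_plate_layout(
    library: ProbeLibrary | list[LibraryProbe],
    controls: list[ProbeRecord] | None = None,
) -> PlateLayout:
    """Place library probes, then controls, column-major on the plate.

    The published pipetting scheme interleaves four 96-well stock plates;
    since the exact interleave is robot configuration, the default layout
    is a plain deterministic column-major fill (A1, B1, ... P1, A2, ...)
    with the controls in the wells after the library block. Remaining
    wells stay empty.
    """
    probes = library.probes if isinstance(library, ProbeLibrary) else library
    if controls is None:
        controls = default_controls()
    records = [
        ProbeRecord(p.probe_id, p.variable_region, p.probe_class, p.source)
        if isinstance(p, LibraryProbe)
        else p
        for p in probes
    ] + list(controls)
    order = all_wells()
    if len(records) > len(order):
        raise ValueError(f"{len(records)} probes exceed the {N_WELLS}-well plate")
    return PlateLayout(wells=dict(zip(order, records)))


@dataclass
class PlateReadout:
    """Raw absorbance per well for one protein extract."""

    values: dict[str, float]
    plate_id: str = "plate1"
    extract_id: str = ""

    def missing_wells(self) -> list[str]:
        return sort_wells(set(all_wells()) - set(self.values))

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, name="absorbance")


def read_readout(path, dialect: str = "auto") -> PlateReadout:
    """Read a readout CSV in grid (16 x 24) or long (well,value) dialect.

    Grid files have row labels A..P and column labels 1..24; long files
    need a header with ``well`` and ``value`` columns. Negative values
    are kept (with a warning attached by the caller's logging); duplicate
    wells are an error.
    """
    head = pd.read_csv(path, nrows=1)
    if dialect == "auto":
        dialect = "long" if "well" in [c.lower() for c in head.columns] else "grid"
    if dialect == "long":
        df = pd.read_csv(path)
        df.columns = [c.lower() for c in df.columns]
        if "well" not in df.columns or "value" not in df.columns:
            raise ValueError("long readout needs 'well' and 'value' columns")
        if df["well"].duplicated().any():
            dups = df["well"][df["well"].duplicated()].tolist()
            raise ValueError(f"duplicate wells in readout: {dups}")
        values = dict(zip(df["well"].astype(str), df["value"].astype(float)))
    elif dialect == "grid":
        df = pd.read_csv(path, index_col=0)
        values = {}
        for row_label, row in df.iterrows():
            for col_label, v in row.items():
                if pd.isna(v):
                    continue
                values[f"{row_label}{int(col_label)}"] = float(v)
    else:
        raise ValueError(f"unknown readout dialect {dialect!r}")
    bad = {w for w in values if w[0] not in PLATE_ROWS or not w[1:].isdigit()}
    if bad:
        raise ValueError(f"malformed well names: {sorted(bad)[:5]}")
    return PlateReadout(values=values)


def write_readout(readout: PlateReadout, path, dialect: str = "grid") -> None:
    if dialect == "long":
        df = pd.DataFrame(
            {"well": list(readout.values), "value": list(readout.values.values())}
        )
        df.to_csv(path, index=False)
    elif dialect == "grid":
        grid = pd.DataFrame(
            index=list(PLATE_ROWS), columns=[str(c) for c in PLATE_COLS], dtype=float
        )
        for w, v in readout.values.items():
            grid.loc[w[0], w[1:]] = v
        grid.to_csv(path)
    else:
        raise ValueError(f"unknown readout dialect {dialect!r}")
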