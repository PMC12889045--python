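"""96-well plate layout for single-cell dispensing runs.

The dispenser fills the first 11 columns of a 96-well plate (wells A1–H11,
88 wells). The last column is reserved for controls: blanks in A12–C12
(no droplets at all), non-template controls in D12–G12 (droplets verified
empty of cells, used as fluorescence background) and a 400-droplet positive
control in H12.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

ROWS = "ABCDEFGH"
ROLES = ("dispensed", "blank", "ntc", "positive")

_WELL_RE = re.compile(r"^([A-Ha-h])0?([1-9]|1[0-2])$")


def normalize_well_id(well: str) -> str:
    """Canonicalize a well id to row-letter + 1-based column, e.g. ``A1``.

    Accepts zero-padded forms such as ``A01`` and lower-case rows.
    """
    m = _WELL_RE.match(str(well).strip())
    if m is None:
        raise ValueError(f"not a 96-well id: {well!r}")
    return m.group(1).upper() + m.group(2)


def well_ids(n_rows: int = 8, n_cols: int = 12) -> list[str]:
    """All well ids in row-major order (A1, A2, ..., H12)."""
    return [f"{ROWS[r]}{c + 1}" for r in range(n_rows) for c in range(n_cols)]


@dataclass(frozen=True)
class PlateLayout:
    """Role assignment for every well of a dispensing plate.

    Parameters
    ----------
    n_rows, n_cols
        Plate geometry; the default is a standard 96-well plate.
    role_map
        Mapping well id -> role, one of ``dispensed``, ``blank``, ``ntc``,
        ``positive``. Every well must carry exactly one role.
    """

    n_rows: int = 8
    n_cols: int = 12
    role_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if not self.role_map:
            object.__setattr__(self, "role_map", _default_role_map())
        expected = set(well_ids(self.n_rows, self.n_cols))
        got = set(self.role_map)
        if got != expected:
            missing = sorted(expected - got)
            extra = sorted(got - expected)
            raise ValueError(
                f"role_map must cover every well exactly once; "
                f"missing={missing[:5]} extra={extra[:5]}"
            )
        bad = {w: r for w, r in self.role_map.items() if r not in ROLES}
        if bad:
            raise ValueError(f"unknown roles: {bad}")

    def wells_with_role(self, role: str) -> list[str]:
        if role not in ROLES:
            raise ValueError(f"unknown role {role!r}")
        order = {w: i for i, w in enumerate(well_ids(self.n_rows, self.n_cols))}
        return sorted(
            (w for w, r in self.role_map.items() if r == role),
            key=order.__getitem__,
        )

    @property
    def dispensed_wells(self) -> list[str]:
        return self.wells_with_role("dispensed")

    @property
    def ntc_wells(self) -> list[str]:
        return self.wells_with_role("ntc")

    @property
    def blank_wells(self) -> list[str]:
        return self.wells_with_role("blank")

    def background_wells(self, background_roles: tuple[str, ...] = ("ntc",)) -> list[str]:
        """Wells pooled to estimate background fluorescence."""
        out: list[str] = []
        for role in background_roles:
            out.extend(self.wells_with_role(role))
        return out


def _default_role_map() -> dict[str, str]:
    role_map: dict[str, str] = {}
    for w in well_ids():
        row, col = w[0], int(w[1:])
        if col <= 11:
            role_map[w] = "dispensed"
        elif row in "ABC":
            role_map[w] = "blank"
        elif row in "DEFG":
            role_map[w] = "ntc"
        else:  # H12
            role_map[w] = "positive"
    return role_map


def default_layout() -> PlateLayout:
    """The study layout: 88 dispensed wells (columns 1–11), blanks A12–C12,
    NTCs D12–G12, positive control H12."""
    return PlateLayout()
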