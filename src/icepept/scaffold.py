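"""Cyclic ice-binding peptide scaffold, mutants, and mutational-activity logic.

The scaffold is a 14-residue cyclic peptide closed by a single disulfide
bridge (Cys3–Cys13).  Four cysteines sit at positions 2, 3, 7 and 13;
threonines at 4, 10 and 14; aspartate at 8.  The identities of the six
remaining positions are not public, so they are filled with glycine and
flagged as placeholders — analyses that depend on them operate on a
synthetic stand-in, not the real sequence.

Ice-recrystallization-inhibition (IRI) activity of variants is recorded as
the mean-grain-area ratio to a buffer control (mga_ratio); a variant is
"active" when that ratio falls below a configurable threshold.  A residue is
called *essential* when some single-point substitution at its position
abolishes activity.
"""

from __future__ import annotations

import dataclasses
import json
import re
import warnings
from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

AA1 = set("ACDEFGHIKLMNPQRSTVWY")

#: canonical residue map (1-based position -> one-letter code)
CANONICAL_RESIDUES = {2: "C", 3: "C", 7: "C", 13: "C",
                      4: "T", 10: "T", 14: "T",
                      8: "D"}
PLACEHOLDER_POSITIONS = frozenset({1, 5, 6, 9, 11, 12})
SCAFFOLD_LENGTH = 14
DEFAULT_ACTIVITY_THRESHOLD = 0.8


class ScaffoldError(ValueError):
    pass


@dataclass(frozen=True)
class PeptideScaffold:
    """A peptide sequence with disulfide topology and redox state."""

    residues: tuple[str, ...]
    disulfide_pairs: tuple[tuple[int, int], ...] = ()
    redox_state: str = "oxidized"
    placeholder_positions: frozenset[int] = frozenset()

    def __post_init__(self):
        for aa in self.residues:
            if aa not in AA1:
                raise ScaffoldError(f"unknown residue code {aa!r}")
        if self.redox_state not in ("oxidized", "reduced"):
            raise ScaffoldError(f"redox_state must be oxidized|reduced, got {self.redox_state!r}")
        if self.redox_state == "reduced" and self.disulfide_pairs:
            raise ScaffoldError("reduced scaffold cannot carry disulfide pairs")
        seen: set[int] = set()
        for i, j in self.disulfide_pairs:
            for p in (i, j):
                if not 1 <= p <= len(self.residues):
                    raise ScaffoldError(f"disulfide position {p} out of range")
                if self.residues[p - 1] != "C":
                    raise ScaffoldError(f"disulfide position {p} is not Cys")
                if p in seen:
                    raise ScaffoldError(f"position {p} appears in two disulfide pairs")
                seen.add(p)

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(self.residues)

    @property
    def is_cyclic(self) -> bool:
        return len(self.disulfide_pairs) > 0

    def residue(self, position: int) -> str:
        if not 1 <= position <= len(self.residues):
            raise ScaffoldError(f"position {position} out of range 1..{len(self.residues)}")
        return self.residues[position - 1]

    def positions_of(self, aa: str) -> list[int]:
        return [i + 1 for i, r in enumerate(self.residues) if r == aa]

    # -- serialization -------------------------------------------------
    def to_record(self) -> str:
        ss = ",".join(f"{i}-{j}" for i, j in self.disulfide_pairs)
        ph = ",".join(str(p) for p in sorted(self.placeholder_positions))
        return f"{self.sequence}|ss={ss}|redox={self.redox_state}|placeholders={ph}"

    @classmethod
    def from_record(cls, record: str) -> "PeptideScaffold":
        seq, ss, redox, ph = record.split("|")
        pairs = tuple(
            tuple(int(x) for x in p.split("-"))
            for p in ss.removeprefix("ss=").split(",") if p
        )
        placeholders = frozenset(
            int(x) for x in ph.removeprefix("placeholders=").split(",") if x
        )
        return cls(tuple(seq), pairs, redox.removeprefix("redox="), placeholders)

    def to_json(self) -> str:
        return json.dumps({
            "sequence": self.sequence,
            "disulfide_pairs": [list(p) for p in self.disulfide_pairs],
            "redox_state": self.redox_state,
            "placeholder_positions": sorted(self.placeholder_positions),
        })

    @classmethod
    def from_json(cls, text: str) -> "PeptideScaffold":
        d = json.loads(text)
        return cls(
            tuple(d["sequence"]),
            tuple(tuple(p) for p in d["disulfide_pairs"]),
            d["redox_state"],
            frozenset(d["placeholder_positions"]),
        )


def build_canonical_scaffold() -> PeptideScaffold:
    """The canonical 14-residue oxidized scaffold with the Cys3–Cys13 bridge.

    Positions 1, 5, 6, 9, 11 and 12 are glycine placeholders (the true
    residues are not recoverable from public data) and are flagged as such.
    """
    residues = tuple(
        CANONICAL_RESIDUES.get(p, "G") for p in range(1, SCAFFOLD_LENGTH + 1)
    )
    return PeptideScaffold(
        residues=residues,
        disulfide_pairs=((3, 13),),
        redox_state="oxidized",
        placeholder_positions=PLACEHOLDER_POSITIONS,
    )


def apply_mutation(scaffold: PeptideScaffold,
                   substitutions: list[tuple[int, str]]) -> PeptideScaffold:
    """Apply point substitutions, pruning any disulfide pair whose Cys is lost.

    Substituting a placeholder position emits a warning: the outcome depends
    on a residue identity that is itself a synthetic stand-in.
    """
    residues = list(scaffold.residues)
    for pos, to_aa in substitutions:
        if not 1 <= pos <= len(residues):
            raise ScaffoldError(f"substitution position {pos} out of range 1..{len(residues)}")
        if to_aa not in AA1:
            raise ScaffoldError(f"unknown residue code {to_aa!r}")
        if pos in scaffold.placeholder_positions:
            warnings.warn(
                f"position {pos} is a placeholder (synthetic identity); "
                "mutation outcome is a stand-in", stacklevel=2)
        residues[pos - 1] = to_aa
    mutated = set(p for p, _ in substitutions)
    pairs = tuple(
        (i, j) for i, j in scaffold.disulfide_pairs
        if not ((i in mutated and residues[i - 1] != "C")
                or (j in mutated and residues[j - 1] != "C"))
    )
    return PeptideScaffold(tuple(residues), pairs, scaffold.redox_state,
                           scaffold.placeholder_positions)


# ---------------------------------------------------------------------------
# substitution string codec: "T10S;T14S"
_SUB_RE = re.compile(r"^([A-Z])(\d+)([A-Z])$")


def parse_substitutions(code: str) -> list[tuple[int, str, str]]:
    """Parse "T10S;T14S" into [(10, 'T', 'S'), (14, 'T', 'S')]."""
    if not code:
        return []
    out = []
    for token in code.split(";"):
        m = _SUB_RE.match(token.strip())
        if not m:
            raise ScaffoldError(f"bad substitution token {token!r}")
        out.append((int(m.group(2)), m.group(1), m.group(3)))
    return out


def format_substitutions(subs: list[tuple[int, str, str]]) -> str:
    return ";".join(f"{f}{p}{t}" for p, f, t in subs)


@dataclass
class MutationalActivityTable:
    """Variants × concentration with mean-grain-area ratios and activity calls.

    ``active`` is defined as mga_ratio < activity_threshold.  Substitutions
    are validated against the canonical scaffold (the recorded from-residue
    must match).
    """

    frame: pd.DataFrame
    activity_threshold: float = DEFAULT_ACTIVITY_THRESHOLD
    _COLUMNS = ("variant_id", "substitutions", "redox_state",
                "concentration", "mga_ratio")

    def __post_init__(self):
        missing = set(self._COLUMNS) - set(self.frame.columns)
        if missing:
            raise ScaffoldError(f"activity table missing columns {sorted(missing)}")
        df = self.frame.copy()
        df["substitutions"] = df["substitutions"].fillna("")
        if (df["mga_ratio"] <= 0).any():
            raise ScaffoldError("mga_ratio must be positive")
        canonical = build_canonical_scaffold()
        for code in df["substitutions"]:
            for pos, from_aa, _ in parse_substitutions(code):
                if canonical.residue(pos) != from_aa:
                    raise ScaffoldError(
                        f"substitution {from_aa}{pos}: canonical residue at "
                        f"{pos} is {canonical.residue(pos)}")
        df["active"] = df["mga_ratio"] < self.activity_threshold
        self.frame = df

    # -- I/O -----------------------------------------------------------
    @classmethod
    def from_csv(cls, path, activity_threshold: float = DEFAULT_ACTIVITY_THRESHOLD):
        df = pd.read_csv(path, comment="#", keep_default_na=False,
                         na_values=[], dtype={"substitutions": str})
        df["concentration"] = df["concentration"].astype(float)
        df["mga_ratio"] = df["mga_ratio"].astype(float)
        return cls(df, activity_threshold)

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    def to_json(self) -> str:
        return self.frame.to_json(orient="records")

    # -- queries ---------------------------------------------------------
    def at_concentration(self, concentration: float) -> pd.DataFrame:
        df = self.frame
        return df[abs(df["concentration"] - concentration) < 1e-9]

    def parent_rows(self, concentration: float) -> pd.DataFrame:
        df = self.at_concentration(concentration)
        return df[(df["substitutions"] == "") & (df["redox_state"] == "oxidized")]


def essential_residues(table: MutationalActivityTable,
                       concentration: float) -> set[int]:
    """Positions where a single-point substitution abolishes activity.

    Requires the oxidized, unsubstituted parent to be present and active at
    the given concentration — without an active parent, "loss of activity"
    is undefined.  Multi-substitution variants (Cys pairs, all-Thr,
    scrambles) never contribute: their loss of activity cannot be pinned on
    one position.
    """
    parents = table.parent_rows(concentration)
    if parents.empty:
        raise ScaffoldError(
            f"parent peptide absent at {concentration} mg/mL; essentiality undefined")
    if not parents["active"].all():
        raise ScaffoldError(
            f"parent peptide inactive at {concentration} mg/mL; essentiality undefined")
    out: set[int] = set()
    for _, row in table.at_concentration(concentration).iterrows():
        subs = parse_substitutions(row["substitutions"])
        if len(subs) == 1 and row["redox_state"] == "oxidized" and not row["active"]:
            out.add(subs[0][0])
    return out


def load_packaged_activity_table(
        activity_threshold: float = DEFAULT_ACTIVITY_THRESHOLD) -> MutationalActivityTable:
    """The packaged variant-activity fixture (transcribed activity calls;
    the numeric mga_ratio values are representative, the calls are the data)."""
    ref = resources.files("icepept.data").joinpath("mutational_activity.csv")
    with resources.as_file(ref) as path:
        return MutationalActivityTable.from_csv(path, activity_threshold)
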