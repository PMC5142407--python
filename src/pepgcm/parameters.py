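"""Model parameter tables: per-residue free energies, Ala-X pair free
energies, per-(residue, class) alpha scale factors, and scalar constants.

All energies are kJ/mol. The packaged defaults carry the MD-derived values
of the dodecane-water group-contribution model; users may point
:func:`load_parameters` at a directory with the same CSV/YAML schemas to
substitute their own tables (e.g. a different hydropathy partition or turn
scale).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml

from .errors import ParameterError, UnknownResidueError

STANDARD_CODES: str = "ACDEFGHIKLMNPQRSTVWY"
CLASSES: tuple[str, str] = ("C1", "C2")

#: Boltzmann constant, kJ/(mol K)
KB: float = 0.0083144621

_RESIDUE_COLUMNS = ["code", "name3", "dg_kjmol", "dg_unc_kjmol", "hydropathy", "turn_propensity"]
_PAIR_COLUMNS = ["base", "partner", "dg_kjmol", "dg_unc_kjmol"]
_ALPHA_COLUMNS = ["code", "cls", "alpha"]


@dataclass(frozen=True)
class ResidueParameters:
    """Single-residue record: interface insertion free energy and annotations."""

    code: str
    name3: str
    dg: float
    dg_uncertainty: float
    hydropathy: str  # "nonpolar" | "polar"
    turn_propensity: float


@dataclass(frozen=True)
class PairParameters:
    """Ala-``partner`` dipeptide free energy."""

    partner: str
    dg_pair: float
    dg_pair_uncertainty: float


@dataclass(frozen=True)
class AlphaParameter:
    """Scale factor for one (residue, neighbour-class) combination."""

    code: str
    cls: str  # "C1" | "C2"
    alpha: float


@dataclass(frozen=True)
class ModelConstants:
    pearson_threshold: float = 0.40
    correction_slope: float = 292.8
    correction_intercept: float = 86.6
    kB: float = KB
    T_default: float = 300.0


@dataclass(frozen=True)
class ParameterSet:
    """The complete, validated parameter state of the model."""

    residues: Mapping[str, ResidueParameters]
    pairs: Mapping[str, PairParameters]
    alphas: Mapping[tuple[str, str], AlphaParameter]
    constants: ModelConstants = field(default_factory=ModelConstants)
    provenance: str = "packaged"

    # -- lookups ---------------------------------------------------------
    def residue(self, code: str) -> ResidueParameters:
        try:
            return self.residues[code]
        except KeyError:
            raise UnknownResidueError(code) from None

    def dg(self, code: str) -> float:
        """Free-energy contribution of one residue, kJ/mol."""
        return self.residue(code).dg

    def dg_pair(self, partner: str) -> float:
        """Free energy of the Ala-``partner`` pair, kJ/mol."""
        try:
            return self.pairs[partner].dg_pair
        except KeyError:
            raise ParameterError(f"no Ala-pair entry for partner {partner!r}") from None

    def alpha(self, code: str, cls: str) -> float:
        try:
            return self.alphas[(code, cls)].alpha
        except KeyError:
            raise ParameterError(f"no alpha entry for ({code!r}, {cls!r})") from None

    def hydropathy(self, code: str) -> str:
        return self.residue(code).hydropathy

    def turn_propensity(self, code: str) -> float:
        return self.residue(code).turn_propensity

    def with_alphas(self, alphas: Iterable[AlphaParameter]) -> "ParameterSet":
        """Copy of this set with the alpha table replaced (used by fitting)."""
        table = {(a.code, a.cls): a for a in alphas}
        new = replace(self, alphas=table)
        _validate(new)
        return new

    def checksum(self) -> str:
        """SHA-256 over the canonical decimal rendering of every table."""
        lines = []
        for code in sorted(self.residues):
            r = self.residues[code]
            lines.append(f"R,{r.code},{r.name3},{r.dg:.2f},{r.dg_uncertainty:.2f},{r.hydropathy},{r.turn_propensity:.2f}")
        for partner in sorted(self.pairs):
            p = self.pairs[partner]
            lines.append(f"P,{p.partner},{p.dg_pair:.2f},{p.dg_pair_uncertainty:.2f}")
        for key in sorted(self.alphas):
            a = self.alphas[key]
            lines.append(f"A,{a.code},{a.cls},{a.alpha:.2f}")
        c = self.constants
        lines.append(f"C,{c.pearson_threshold},{c.correction_slope},{c.correction_intercept},{c.kB},{c.T_default}")
        return hashlib.sha256("\n".join(lines).encode()).hexdigest()


def lookup_dg(params: ParameterSet, code: str) -> float:
    """Free-energy contribution (kJ/mol) of residue ``code``.

    Raises :class:`UnknownResidueError` for anything outside the twenty
    standard symbols (including B, J, O, U, X, Z).
    """
    return params.dg(code)


# ---------------------------------------------------------------------------
# loading / writing
# ---------------------------------------------------------------------------

def _read_csv(path: Path, columns: list[str], table: str) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, comment="#", skip_blank_lines=True, dtype=str)
    except Exception as exc:  # parse failure
        raise ParameterError(f"cannot parse {table} table {path}: {exc}") from exc
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ParameterError(f"{table} table {path} lacks columns {missing}")
    return df


def _num(value, table: str, row: str, column: str) -> float:
    try:
        return float(value)
    except (TypeError, ValueError):
        raise ParameterError(
            f"non-numeric value {value!r} in {table} table, row {row!r}, column {column!r}"
        ) from None


def load_parameters(path_or_default: str | Path | None = None) -> ParameterSet:
    """Load a :class:`ParameterSet`.

    ``None`` (the default) loads the packaged tables; otherwise
    ``path_or_default`` is a directory containing ``residues.csv``,
    ``pairs.csv``, ``alphas.csv`` and optionally ``constants.yaml``.
    """
    if path_or_default is None:
        root = resources.files("pepgcm") / "data"
        provenance = "packaged"
    else:
        root = Path(path_or_default)
        provenance = str(root)

    with resources.as_file(root) if path_or_default is None else _nullcontext(root) as base:
        base = Path(base)
        rdf = _read_csv(base / "residues.csv", _RESIDUE_COLUMNS, "residue")
        pdf = _read_csv(base / "pairs.csv", _PAIR_COLUMNS, "pair")
        adf = _read_csv(base / "alphas.csv", _ALPHA_COLUMNS, "alpha")
        const_path = base / "constants.yaml"
        constants = _load_constants(const_path) if const_path.exists() else ModelConstants()

    residues: dict[str, ResidueParameters] = {}
    for _, row in rdf.iterrows():
        code = str(row["code"]).strip()
        if code in residues:
            raise ParameterError(f"duplicate residue {code!r} in residue table")
        residues[code] = ResidueParameters(
            code=code,
            name3=str(row["name3"]).strip(),
            dg=_num(row["dg_kjmol"], "residue", code, "dg_kjmol"),
            dg_uncertainty=_num(row["dg_unc_kjmol"], "residue", code, "dg_unc_kjmol"),
            hydropathy=str(row["hydropathy"]).strip().lower(),
            turn_propensity=_num(row["turn_propensity"], "residue", code, "turn_propensity"),
        )

    pairs: dict[str, PairParameters] = {}
    for _, row in pdf.iterrows():
        base_code = str(row["base"]).strip()
        partner = str(row["partner"]).strip()
        if base_code != "A":
            raise ParameterError(f"pair table row {partner!r}: base must be 'A', got {base_code!r}")
        if partner in pairs:
            raise ParameterError(f"duplicate pair partner {partner!r}")
        pairs[partner] = PairParameters(
            partner=partner,
            dg_pair=_num(row["dg_kjmol"], "pair", partner, "dg_kjmol"),
            dg_pair_uncertainty=_num(row["dg_unc_kjmol"], "pair", partner, "dg_unc_kjmol"),
        )

    alphas: dict[tuple[str, str], AlphaParameter] = {}
    for _, row in adf.iterrows():
        code = str(row["code"]).strip()
        cls = str(row["cls"]).strip()
        key = (code, cls)
        if key in alphas:
            raise ParameterError(f"duplicate alpha entry for ({code}, {cls})")
        alphas[key] = AlphaParameter(code=code, cls=cls, alpha=_num(row["alpha"], "alpha", f"{code}/{cls}", "alpha"))

    params = ParameterSet(residues=residues, pairs=pairs, alphas=alphas,
                          constants=constants, provenance=provenance)
    _validate(params)
    return params


class _nullcontext:
    def __init__(self, value):
        self.value = value

    def __enter__(self):
        return self.value

    def __exit__(self, *exc):
        return False


def _load_constants(path: Path) -> ModelConstants:
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ParameterError(f"constants file {path} must be a mapping")
    known = {f for f in ModelConstants.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise ParameterError(f"unknown constant keys {sorted(unknown)} in {path}")
    return ModelConstants(**{k: float(v) for k, v in raw.items()})


def _validate(params: ParameterSet) -> None:
    codes = set(params.residues)
    if codes != set(STANDARD_CODES):
        missing = sorted(set(STANDARD_CODES) - codes)
        extra = sorted(codes - set(STANDARD_CODES))
        raise ParameterError(f"residue table must hold exactly the 20 standard codes; missing {missing}, extra {extra}")
    for r in params.residues.values():
        if not r.dg < 0:
            raise ParameterError(f"residue {r.code}: dg must be negative, got {r.dg}")
        if not r.dg_uncertainty > 0:
            raise ParameterError(f"residue {r.code}: dg_uncertainty must be positive, got {r.dg_uncertainty}")
        if not r.turn_propensity > 0:
            raise ParameterError(f"residue {r.code}: turn_propensity must be positive, got {r.turn_propensity}")
        if r.hydropathy not in ("nonpolar", "polar"):
            raise ParameterError(f"residue {r.code}: hydropathy must be 'nonpolar' or 'polar', got {r.hydropathy!r}")
    if set(params.pairs) != codes:
        raise ParameterError("pair table partners must be a permutation of the residue codes")
    for p in params.pairs.values():
        if not p.dg_pair < 0:
            raise ParameterError(f"pair Ala-{p.partner}: dg_pair must be negative, got {p.dg_pair}")
    expected = {(c, cls) for c in codes for cls in CLASSES}
    if set(params.alphas) != expected:
        raise ParameterError("alpha table must hold exactly 40 entries: every residue in classes C1 and C2")
    for a in params.alphas.values():
        if not a.alpha > 0:
            raise ParameterError(f"alpha({a.code}, {a.cls}) must be positive, got {a.alpha}")
    c = params.constants
    if not 0 < c.pearson_threshold < 1:
        raise ParameterError(f"pearson_threshold must lie in (0, 1), got {c.pearson_threshold}")
    if c.correction_slope <= 0 or c.correction_intercept <= 0:
        raise ParameterError("correction slope and intercept must be positive")


def write_parameters(params: ParameterSet, directory: str | Path) -> None:
    """Write the four parameter files with the load_parameters schemas.

    Numeric cells keep two decimals so a write/load round trip reproduces the
    decimal strings of the packaged tables exactly.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    with open(directory / "residues.csv", "w", encoding="utf-8") as fh:
        fh.write(",".join(_RESIDUE_COLUMNS) + "\n")
        for code in sorted(params.residues):
            r = params.residues[code]
            fh.write(f"{r.code},{r.name3},{r.dg:.2f},{r.dg_uncertainty:.2f},{r.hydropathy},{r.turn_propensity:.2f}\n")
    with open(directory / "pairs.csv", "w", encoding="utf-8") as fh:
        fh.write(",".join(_PAIR_COLUMNS) + "\n")
        for partner in sorted(params.pairs):
            p = params.pairs[partner]
            fh.write(f"A,{p.partner},{p.dg_pair:.2f},{p.dg_pair_uncertainty:.2f}\n")
    with open(directory / "alphas.csv", "w", encoding="utf-8") as fh:
        fh.write(",".join(_ALPHA_COLUMNS) + "\n")
        for key in sorted(params.alphas):
            a = params.alphas[key]
            fh.write(f"{a.code},{a.cls},{a.alpha:.2f}\n")
    c = params.constants
    with open(directory / "constants.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(
            {
                "pearson_threshold": c.pearson_threshold,
                "correction_slope": c.correction_slope,
                "correction_intercept": c.correction_intercept,
                "kB": c.kB,
                "T_default": c.T_default,
            },
            fh,
            sort_keys=True,
        )
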