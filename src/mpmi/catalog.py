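"""Marker-reaction and qPCR-primer catalog.

The Microbiome Protein Metabolism Index (MPMI) is computed over a fixed
catalog of 22 Enzyme Commission (EC) reactions tied to microbial nitrogen
and protein metabolism.  Each reaction plays one of two roles:

* ``N`` (numerator) — desirable protein assimilation (polyamine
  biosynthesis, SCFA/BCFA synthesis from amino acids, urea-cycle injection);
* ``D`` (denominator) — undesirable putrefaction (ammonia, hydrogen
  sulfide, uric-acid release).

Four of the reactions double as targets of the qPCR assay; each carries a
blended set of four primer pairs, plus one universal 16S rDNA pair used for
total-bacterial-load normalization (stored under the reserved marker id
``"16S"``).

The catalog ships with the package as two TSV files and can be partially
overridden from user-supplied files with the same schema.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

EC_PATTERN = re.compile(r"^\d+\.\d+\.\d+\.\d+$")
KO_PATTERN = re.compile(r"^K\d{5}$")
#: IUPAC DNA codes accepted in primers (degenerate codes occur in the 16S pair).
IUPAC_DNA = set("ACGTSYRMWKBDHVN")

QPCR_MARKERS = ("2.3.1.109", "2.6.1.19", "3.5.3.12", "2.8.3.18")
SIXTEEN_S = "16S"


class CatalogError(ValueError):
    """Raised when a catalog file fails validation."""


@dataclass(frozen=True)
class MarkerReaction:
    """One catalog entry: an EC reaction and its role in the index."""

    ec_number: str
    kegg_ids: tuple[str, ...]
    role: str  # "N" or "D"
    stoich_weight: float = 1.0
    is_qpcr_marker: bool = False
    representative_genes: str = ""
    representative_enzymes: str = ""
    #: True when a listed KO id does not match K#####; kept verbatim.
    suspect: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        if not EC_PATTERN.match(self.ec_number):
            raise CatalogError(f"malformed EC number: {self.ec_number!r}")
        if self.role not in ("N", "D"):
            raise CatalogError(
                f"unknown role {self.role!r} for EC {self.ec_number}"
            )
        if not self.stoich_weight > 0:
            raise CatalogError(
                f"stoich_weight must be > 0 for EC {self.ec_number}"
            )
        object.__setattr__(
            self,
            "suspect",
            any(not KO_PATTERN.match(k) for k in self.kegg_ids),
        )


@dataclass(frozen=True)
class PrimerPair:
    """A forward/reverse qPCR primer pair for one marker reaction."""

    pair_id: str
    forward_seq: str
    reverse_seq: str


@dataclass(frozen=True)
class PrimerValidation:
    valid: bool
    forward_length: int
    reverse_length: int
    problems: tuple[str, ...]


def _check_seq(seq: str, which: str) -> list[str]:
    problems = []
    if not seq:
        problems.append(f"empty {which} sequence")
        return problems
    if seq != seq.upper():
        problems.append(f"{which} sequence not uppercase")
    bad = sorted(set(seq.upper()) - IUPAC_DNA)
    if bad:
        problems.append(f"non-DNA character(s) {''.join(bad)} in {which} sequence")
    return problems


def validate_primer(pair: PrimerPair) -> PrimerValidation:
    """Report-only sanity check of a primer pair's alphabet and length.

    Degenerate IUPAC codes are accepted (the universal 16S pair uses
    S/Y/R/M).  Melting temperature is out of scope.
    """
    problems = _check_seq(pair.forward_seq, "forward") + _check_seq(
        pair.reverse_seq, "reverse"
    )
    return PrimerValidation(
        valid=not problems,
        forward_length=len(pair.forward_seq),
        reverse_length=len(pair.reverse_seq),
        problems=tuple(problems),
    )


def _read_tsv(path_or_buf) -> pd.DataFrame:
    return pd.read_csv(path_or_buf, sep="\t", dtype=str, keep_default_na=False)


def _markers_from_frame(df: pd.DataFrame) -> list[MarkerReaction]:
    required = {"ec_number", "kegg_ids", "role", "stoich_weight", "qpcr_marker"}
    missing = required - set(df.columns)
    if missing:
        raise CatalogError(f"marker table missing columns: {sorted(missing)}")
    markers = []
    seen: set[str] = set()
    for i, row in df.iterrows():
        ec = row["ec_number"].strip()
        if ec in seen:
            raise CatalogError(f"duplicate ec_number {ec!r} at row {i}")
        seen.add(ec)
        try:
            markers.append(
                MarkerReaction(
                    ec_number=ec,
                    kegg_ids=tuple(
                        k.strip() for k in row["kegg_ids"].split(",") if k.strip()
                    ),
                    role=row["role"].strip(),
                    stoich_weight=float(row["stoich_weight"]),
                    is_qpcr_marker=row["qpcr_marker"].strip() == "1",
                    representative_genes=row.get("representative_genes", ""),
                    representative_enzymes=row.get("representative_enzymes", ""),
                )
            )
        except CatalogError as err:
            raise CatalogError(f"row {i} ({ec!r}): {err}") from err
    return markers


def _primers_from_frame(df: pd.DataFrame) -> dict[str, list[PrimerPair]]:
    required = {"ec_number", "pair_id", "forward", "reverse"}
    missing = required - set(df.columns)
    if missing:
        raise CatalogError(f"primer table missing columns: {sorted(missing)}")
    primers: dict[str, list[PrimerPair]] = {}
    for i, row in df.iterrows():
        pair = PrimerPair(
            pair_id=row["pair_id"].strip(),
            forward_seq=row["forward"].strip(),
            reverse_seq=row["reverse"].strip(),
        )
        report = validate_primer(pair)
        if not report.valid:
            raise CatalogError(
                f"primer row {i} ({pair.pair_id}): {'; '.join(report.problems)}"
            )
        primers.setdefault(row["ec_number"].strip(), []).append(pair)
    return primers


def _validate_catalog(
    markers: list[MarkerReaction], primers: dict[str, list[PrimerPair]]
) -> None:
    qpcr = sorted(m.ec_number for m in markers if m.is_qpcr_marker)
    if qpcr != sorted(QPCR_MARKERS):
        raise CatalogError(f"expected qPCR markers {QPCR_MARKERS}, got {qpcr}")
    for ec in QPCR_MARKERS:
        n = len(primers.get(ec, []))
        if n != 4:
            raise CatalogError(f"marker {ec} has {n} primer pairs, expected 4")
    if SIXTEEN_S not in primers:
        raise CatalogError("universal 16S primer pair missing")


def load_catalog(
    override_path: str | Path | None = None,
    primer_override_path: str | Path | None = None,
) -> tuple[list[MarkerReaction], dict[str, list[PrimerPair]]]:
    """Load the embedded marker/primer catalog, optionally overridden.

    Parameters
    ----------
    override_path
        Optional TSV replacing marker entries by ``ec_number``.  Schema:
        ``ec_number  kegg_ids(comma-sep)  role  stoich_weight  qpcr_marker``.
    primer_override_path
        Optional TSV replacing the primer list of any marker it mentions.
        Schema: ``ec_number  pair_id  forward  reverse``.

    Returns
    -------
    (markers, primers)
        22 :class:`MarkerReaction` entries (12 numerator, 10 denominator)
        and a marker-id → list-of-:class:`PrimerPair` map (4 pairs per qPCR
        marker plus the universal 16S pair).
    """
    data = resources.files("mpmi.data")
    markers = _markers_from_frame(_read_tsv(data / "markers.tsv"))
    primers = _primers_from_frame(_read_tsv(data / "primers.tsv"))

    if override_path is not None:
        override = _markers_from_frame(_read_tsv(override_path))
        by_ec = {m.ec_number: m for m in markers}
        for m in override:
            by_ec[m.ec_number] = m
        markers = list(by_ec.values())
    if primer_override_path is not None:
        for ec, pairs in _primers_from_frame(_read_tsv(primer_override_path)).items():
            primers[ec] = pairs

    _validate_catalog(markers, primers)
    return markers, primers


def numerator_set(markers: list[MarkerReaction] | None = None) -> set[str]:
    """EC numbers whose abundance enters the MPMI numerator."""
    if markers is None:
        markers, _ = load_catalog()
    return {m.ec_number for m in markers if m.role == "N"}


def denominator_set(markers: list[MarkerReaction] | None = None) -> set[str]:
    """EC numbers whose abundance enters the MPMI denominator."""
    if markers is None:
        markers, _ = load_catalog()
    return {m.ec_number for m in markers if m.role == "D"}


def write_catalog(
    markers: list[MarkerReaction],
    primers: dict[str, list[PrimerPair]],
    marker_path: str | Path,
    primer_path: str | Path,
) -> None:
    """Serialize a catalog back to the documented TSV schema (round-trips)."""
    mrows = [
        {
            "ec_number": m.ec_number,
            "kegg_ids": ",".join(m.kegg_ids),
            "role": m.role,
            "stoich_weight": m.stoich_weight,
            "qpcr_marker": int(m.is_qpcr_marker),
            "representative_genes": m.representative_genes,
            "representative_enzymes": m.representative_enzymes,
        }
        for m in markers
    ]
    pd.DataFrame(mrows).to_csv(marker_path, sep="\t", index=False)
    prows = [
        {
            "ec_number": ec,
            "pair_id": p.pair_id,
            "forward": p.forward_seq,
            "reverse": p.reverse_seq,
        }
        for ec, pairs in primers.items()
        for p in pairs
    ]
    pd.DataFrame(prows).to_csv(primer_path, sep="\t", index=False)
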