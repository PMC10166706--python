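"""From KO-annotated gene counts to normalized EC abundance profiles.

Shotgun-metagenomic gene counts arrive annotated by KEGG Orthology (KO)
identifier.  Downstream analyses work on Enzyme Commission (EC) reactions,
so counts are *regrouped*: every KO's count is summed into each EC it maps
to (a KO mapping to k ECs contributes its full count to each; a fractional
1/k split is available via ``split="fractional"``).

Profiles are then internally normalized per sample by the total regrouped
count of a reference EC set — by default the glycolysis/TCA-cycle core
enzymes, a near-universal energy-metabolism module that serves as a proxy
for total functional sequencing depth.  Normalized profiles are invariant
to per-sample sequencing depth.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: Default normalization set: core glycolysis + TCA-cycle enzymes.  The
#: reference module is supplied as a plain EC list so users can swap in
#: their own definition.
GLYCOLYSIS_TCA_ECS: tuple[str, ...] = (
    # glycolysis
    "2.7.1.1", "5.3.1.9", "2.7.1.11", "4.1.2.13", "5.3.1.1",
    "1.2.1.12", "2.7.2.3", "5.4.2.11", "4.2.1.11", "2.7.1.40",
    # pyruvate -> TCA
    "1.2.4.1", "2.3.3.1", "4.2.1.3", "1.1.1.42", "1.2.4.2",
    "6.2.1.5", "1.3.5.1", "4.2.1.2", "1.1.1.37",
)


class ProfileError(ValueError):
    pass


@dataclass
class GeneCountTable:
    """Samples × KO non-negative integer count matrix."""

    counts: pd.DataFrame  # index = sample ids, columns = KO ids

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates or self.counts.columns.has_duplicates:
            raise ProfileError("duplicate sample or KO labels")
        if (self.counts.to_numpy() < 0).any():
            raise ProfileError("negative counts")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def ko_ids(self) -> list[str]:
        return list(self.counts.columns)


@dataclass
class ECAbundanceMatrix:
    """Samples × EC normalized abundance matrix with pathway annotations.

    ``normalization_denominator`` records, per sample, the pre-normalization
    total of the configured reference EC set; ``unmapped_mass`` the total
    count carried by KOs missing from the KO→EC map.
    """

    abundance: pd.DataFrame  # index = sample ids, columns = EC ids
    pathway_annotation: dict[str, list[str]] = field(default_factory=dict)
    normalization_denominator: pd.Series | None = None
    unmapped_mass: pd.Series | None = None

    @property
    def sample_ids(self) -> list[str]:
        return list(self.abundance.index)

    @property
    def ec_ids(self) -> list[str]:
        return list(self.abundance.columns)


def regroup_ko_to_ec(
    table: GeneCountTable,
    ko_to_ec: dict[str, set[str]],
    split: str = "full",
) -> tuple[pd.DataFrame, pd.Series]:
    """Sum KO counts into EC reactions.

    Parameters
    ----------
    table
        Samples × KO counts.
    ko_to_ec
        KO id → set of EC ids.  KOs absent from the map contribute to the
        per-sample unmapped-mass report instead of the matrix.
    split
        ``"full"`` (default): a KO mapping to k ECs gives its full count to
        each.  ``"fractional"``: each EC receives count/k.

    Returns
    -------
    (ec_counts, unmapped_mass)
        Samples × EC raw count matrix and a per-sample Series of unmapped
        counts.
    """
    if not ko_to_ec:
        raise ProfileError("empty KO→EC mapping")
    if split not in ("full", "fractional"):
        raise ProfileError(f"unknown split mode {split!r}")

    ec_ids = sorted({ec for ecs in ko_to_ec.values() for ec in ecs})
    ec_index = {ec: j for j, ec in enumerate(ec_ids)}
    n_samples = len(table.sample_ids)
    out = np.zeros((n_samples, len(ec_ids)))
    unmapped = np.zeros(n_samples)
    counts = table.counts.to_numpy(dtype=float)
    for j, ko in enumerate(table.ko_ids):
        col = counts[:, j]
        ecs = ko_to_ec.get(ko)
        if not ecs:
            unmapped += col
            continue
        w = 1.0 / len(ecs) if split == "fractional" else 1.0
        for ec in ecs:
            out[:, ec_index[ec]] += w * col
    ec_counts = pd.DataFrame(out, index=table.counts.index, columns=ec_ids)
    return ec_counts, pd.Series(unmapped, index=table.counts.index, name="unmapped")


def normalize(
    ec_counts: pd.DataFrame,
    normalization_ec_set: set[str] | None = None,
    unmapped_mass: pd.Series | None = None,
    pseudocount: float = 0.0,
) -> ECAbundanceMatrix:
    """Divide each sample row by its total count over the reference EC set.

    A sample whose reference total (plus ``pseudocount``) is zero is an
    error — depth cannot be estimated for it.
    """
    ref = set(normalization_ec_set) if normalization_ec_set else set(GLYCOLYSIS_TCA_ECS)
    present = [ec for ec in ec_counts.columns if ec in ref]
    denom = ec_counts[present].sum(axis=1) + pseudocount
    bad = denom[denom <= 0]
    if len(bad):
        raise ProfileError(
            "zero normalization denominator for sample(s): "
            + ", ".join(map(str, bad.index[:5]))
        )
    return ECAbundanceMatrix(
        abundance=ec_counts.div(denom, axis=0),
        normalization_denominator=denom.rename("denominator"),
        unmapped_mass=unmapped_mass,
    )


def annotate_pathways(
    matrix: ECAbundanceMatrix,
    ec_to_pathways: dict[str, list[str]],
    max_pathways: int = 5,
) -> ECAbundanceMatrix:
    """Attach up to ``max_pathways`` ordered KEGG pathway ids per EC.

    ECs missing from the annotation get an empty list; their number is
    logged as a warning count.
    """
    annotation: dict[str, list[str]] = {}
    n_missing = 0
    for ec in matrix.ec_ids:
        paths = ec_to_pathways.get(ec, [])
        if not paths:
            n_missing += 1
        annotation[ec] = list(paths[:max_pathways])
    if n_missing:
        log.warning("%d EC number(s) lack pathway annotation", n_missing)
    matrix.pathway_annotation = annotation
    return matrix


# ---------------------------------------------------------------- file I/O

def read_counts(path: str | Path) -> GeneCountTable:
    """Read a samples × KO counts TSV (header = KO ids, first col = sample)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        raise ProfileError(f"{path}: non-numeric counts")
    if (arr < 0).any():
        i, j = np.argwhere(arr < 0)[0]
        raise ProfileError(
            f"{path}: negative count at line {i + 2} (sample {df.index[i]!r})"
        )
    if not np.allclose(arr, np.round(arr)):
        i, j = np.argwhere(~np.isclose(arr, np.round(arr)))[0]
        raise ProfileError(
            f"{path}: non-integer count at line {i + 2} (sample {df.index[i]!r})"
        )
    df = df.astype(np.int64)
    df.index = df.index.astype(str)
    df.index.name = None
    df.columns.name = None
    return GeneCountTable(counts=df)


def write_counts(table: GeneCountTable, path: str | Path) -> None:
    table.counts.to_csv(path, sep="\t", index_label="sample")


def read_ko_to_ec(path: str | Path) -> dict[str, set[str]]:
    """Read a two-column ``ko<TAB>ec`` mapping file."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    mapping: dict[str, set[str]] = {}
    for ko, ec in zip(df.iloc[:, 0], df.iloc[:, 1]):
        mapping.setdefault(ko, set()).add(ec)
    return mapping


def read_ec_pathways(path: str | Path) -> dict[str, list[str]]:
    """Read an ``ec<TAB>pathway<TAB>rank`` file into ordered pathway lists.

    Duplicate (ec, rank) rows: the last one wins, with a logged warning.
    """
    df = pd.read_csv(path, sep="\t", dtype={"rank": int, 0: str, 1: str})
    dup = df.duplicated(subset=[df.columns[0], df.columns[2]], keep=False)
    if dup.any():
        log.warning("%d duplicate EC/rank annotation rows; last row wins", int(dup.sum()))
    df = df.drop_duplicates(subset=[df.columns[0], df.columns[2]], keep="last")
    out: dict[str, list[str]] = {}
    for ec, grp in df.groupby(df.columns[0], sort=False):
        grp = grp.sort_values(df.columns[2])
        out[str(ec)] = [str(p) for p in grp.iloc[:, 1]]
    return out


def write_matrix(matrix: ECAbundanceMatrix, path: str | Path) -> None:
    """Write the normalized matrix TSV plus a JSON sidecar (denominators,
    unmapped mass, pathway annotation)."""
    path = Path(path)
    matrix.abundance.to_csv(path, sep="\t", index_label="sample")
    sidecar = {
        "normalization_denominator": (
            matrix.normalization_denominator.to_dict()
            if matrix.normalization_denominator is not None
            else None
        ),
        "unmapped_mass": (
            matrix.unmapped_mass.to_dict() if matrix.unmapped_mass is not None else None
        ),
        "pathway_annotation": matrix.pathway_annotation,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_matrix(path: str | Path) -> ECAbundanceMatrix:
    path = Path(path)
    abundance = pd.read_csv(path, sep="\t", index_col=0)
    abundance.index = abundance.index.astype(str)
    matrix = ECAbundanceMatrix(abundance=abundance)
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        if meta.get("normalization_denominator"):
            matrix.normalization_denominator = pd.Series(
                meta["normalization_denominator"]
            )
        if meta.get("unmapped_mass"):
            matrix.unmapped_mass = pd.Series(meta["unmapped_mass"])
        matrix.pathway_annotation = meta.get("pathway_annotation", {})
    return matrix
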