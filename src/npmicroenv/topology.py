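"""Static per-bead annotation of a coarse-grained system.

A :class:`Topology` maps every bead to its molecule, molecule class
(polymer / peptide / water / ion), chemical species label (monomer code or
amino-acid code), copolymer block (PEG / PLGA / none) and position along
that block.  Coordinate files do not carry this information unambiguously,
so it travels as a sidecar CSV/TSV table.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Topology",
    "TopologyError",
    "MOLECULE_CLASSES",
    "BLOCKS",
    "DEFAULT_BEAD_MASS",
    "read_topology",
    "write_topology",
]

MOLECULE_CLASSES = ("polymer", "peptide", "water", "ion")
BLOCKS = ("PEG", "PLGA", "none")

#: Standard coarse-grained bead mass (4:1 heavy-atom mapping), amu.
DEFAULT_BEAD_MASS = 72.0

_COLUMNS = [
    "bead_id",
    "molecule_id",
    "molecule_class",
    "species",
    "block",
    "monomer_index",
    "mass",
]


class TopologyError(ValueError):
    """Raised when a topology table violates its invariants."""


class Topology:
    """Validated per-bead annotation table.

    Parameters
    ----------
    table : DataFrame with columns ``bead_id, molecule_id, molecule_class,
        species, block, monomer_index, mass``.  ``mass`` may be omitted and
        defaults to 72 amu.
    """

    def __init__(self, table: pd.DataFrame):
        table = table.copy()
        if "mass" not in table.columns:
            table["mass"] = DEFAULT_BEAD_MASS
        missing = [c for c in _COLUMNS if c not in table.columns]
        if missing:
            raise TopologyError(f"topology table missing columns: {missing}")
        table = table[_COLUMNS]
        table["bead_id"] = table["bead_id"].astype(int)
        table["molecule_id"] = table["molecule_id"].astype(int)
        table["monomer_index"] = table["monomer_index"].astype(int)
        table["mass"] = table["mass"].astype(float)
        for col in ("molecule_class", "species", "block"):
            table[col] = table[col].astype(str)
        table = table.sort_values("bead_id").reset_index(drop=True)
        self._table = table
        self._validate()

    # -- validation ------------------------------------------------------
    def _validate(self) -> None:
        t = self._table
        n = len(t)
        if n == 0:
            raise TopologyError("topology is empty")
        bead_ids = t["bead_id"].to_numpy()
        if bead_ids[0] != 0 or not np.array_equal(bead_ids, np.arange(n)):
            if len(np.unique(bead_ids)) != n:
                raise TopologyError("duplicate bead_id in topology")
            raise TopologyError("bead_ids must be contiguous 0..N-1")
        bad_class = set(t["molecule_class"]) - set(MOLECULE_CLASSES)
        if bad_class:
            raise TopologyError(f"unknown molecule_class values: {sorted(bad_class)}")
        bad_block = set(t["block"]) - set(BLOCKS)
        if bad_block:
            raise TopologyError(f"unknown block values: {sorted(bad_block)}")
        in_block = t["block"].isin(("PEG", "PLGA"))
        if (t.loc[in_block, "molecule_class"] != "polymer").any():
            raise TopologyError("beads with block PEG/PLGA must be molecule_class polymer")
        # monomer_index strictly increasing along each (molecule, block)
        poly = t[in_block]
        for (_, _), grp in poly.groupby(["molecule_id", "block"], sort=False):
            idx = grp.sort_values("bead_id")["monomer_index"].to_numpy()
            if np.any(np.diff(idx) <= 0):
                raise TopologyError(
                    "monomer_index must be strictly increasing along each block"
                )
        if (t["mass"] <= 0).any():
            raise TopologyError("bead masses must be positive")

    # -- accessors -------------------------------------------------------
    @property
    def table(self) -> pd.DataFrame:
        return self._table

    def __len__(self) -> int:
        return len(self._table)

    @property
    def n_beads(self) -> int:
        return len(self._table)

    @property
    def bead_id(self) -> np.ndarray:
        return self._table["bead_id"].to_numpy()

    @property
    def molecule_id(self) -> np.ndarray:
        return self._table["molecule_id"].to_numpy()

    @property
    def molecule_class(self) -> np.ndarray:
        return self._table["molecule_class"].to_numpy()

    @property
    def species(self) -> np.ndarray:
        return self._table["species"].to_numpy()

    @property
    def block(self) -> np.ndarray:
        return self._table["block"].to_numpy()

    @property
    def monomer_index(self) -> np.ndarray:
        return self._table["monomer_index"].to_numpy()

    @property
    def mass(self) -> np.ndarray:
        return self._table["mass"].to_numpy()

    # -- selection -------------------------------------------------------
    def select(
        self,
        predicate: Callable[[pd.DataFrame], Iterable[bool]] | None = None,
        **field_equals,
    ) -> np.ndarray:
        """Bead ids matching a predicate, in ascending bead_id order.

        Either pass a callable receiving the topology table and returning a
        boolean mask, or keyword equality constraints on the columns, e.g.
        ``select(species="EO")`` or ``select(molecule_class="polymer")``.
        Keyword values may be scalars or collections (membership test).
        """
        mask = np.ones(len(self), dtype=bool)
        if predicate is not None:
            mask &= np.asarray(predicate(self._table), dtype=bool)
        for field, value in field_equals.items():
            if field not in _COLUMNS:
                raise TopologyError(f"unknown topology field: {field!r}")
            col = self._table[field]
            if isinstance(value, (list, tuple, set, frozenset, np.ndarray)):
                mask &= col.isin(list(value)).to_numpy()
            else:
                mask &= (col == value).to_numpy()
        return self.bead_id[mask]

    def beads_of_molecule(self, molecule_id: int) -> np.ndarray:
        """Bead ids of one molecule, in bead_id order."""
        out = self.bead_id[self.molecule_id == molecule_id]
        if len(out) == 0:
            raise TopologyError(f"unknown molecule_id {molecule_id}")
        return out

    def molecules_of_class(self, *classes: str) -> np.ndarray:
        """Sorted unique molecule ids whose class is in ``classes``."""
        mask = np.isin(self.molecule_class, classes)
        return np.unique(self.molecule_id[mask])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Topology):
            return NotImplemented
        return self._table.equals(other._table)


def read_topology(path) -> Topology:
    """Read a topology sidecar table (CSV, or TSV for ``.tsv``/``.txt``)."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    try:
        table = pd.read_csv(path, sep=sep)
    except pd.errors.EmptyDataError as exc:
        raise TopologyError(f"empty topology file: {path}") from exc
    return Topology(table)


def write_topology(topology: Topology, path) -> None:
    """Write the topology table; delimiter chosen from the file suffix."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    topology.table.to_csv(path, sep=sep, index=False)
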