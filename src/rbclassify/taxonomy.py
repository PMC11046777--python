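"""Taxonomy tree: NCBI-dump parsing, LCA, and threshold reduction."""

from __future__ import annotations

import logging
from pathlib import Path

logger = logging.getLogger(__name__)


class TaxonomyError(ValueError):
    pass


class TaxonomyTree:
    """Parent-pointer taxonomy with ranks and optional names.

    Exactly one node (NCBI convention: taxid 1) is its own parent and
    acts as the root; every node must reach the root by parent chasing.
    """

    def __init__(
        self,
        parents: dict[int, int],
        ranks: dict[int, str] | None = None,
        names: dict[int, str] | None = None,
    ) -> None:
        self.parents = dict(parents)
        self.ranks = dict(ranks or {})
        self.names = dict(names or {})
        roots = [t for t, p in self.parents.items() if t == p]
        if len(roots) != 1:
            raise TaxonomyError(f"expected exactly one root, found {len(roots)}")
        self.root = roots[0]
        self._depth: dict[int, int] = {self.root: 0}
        for t in self.parents:
            self.depth(t)

    def __contains__(self, taxid: int) -> bool:
        return taxid in self.parents

    def __len__(self) -> int:
        return len(self.parents)

    def parent(self, taxid: int) -> int:
        try:
            return self.parents[taxid]
        except KeyError:
            raise TaxonomyError(f"unknown taxonomy ID {taxid}") from None

    def depth(self, taxid: int) -> int:
        """Edges from ``taxid`` up to the root."""
        chain = []
        t = taxid
        while t not in self._depth:
            chain.append(t)
            t = self.parent(t)
            if len(chain) > len(self.parents):
                raise TaxonomyError(f"cycle detected at taxonomy ID {taxid}")
        d = self._depth[t]
        for node in reversed(chain):
            d += 1
            self._depth[node] = d
        return self._depth[taxid]

    def path_to_root(self, taxid: int) -> list[int]:
        """Node, its ancestors, ending at the root."""
        if taxid not in self.parents:
            raise TaxonomyError(f"unknown taxonomy ID {taxid}")
        path = [taxid]
        while path[-1] != self.root:
            path.append(self.parent(path[-1]))
        return path

    def is_ancestor(self, anc: int, taxid: int) -> bool:
        """True when ``anc`` is an ancestor-or-self of ``taxid``."""
        return anc in set(self.path_to_root(taxid))

    def lca(self, ids) -> int:
        """Lowest common ancestor of a non-empty set of taxonomy IDs."""
        ids = list(ids)
        if not ids:
            raise TaxonomyError("LCA of an empty set is undefined")
        cur = ids[0]
        if cur not in self.parents:
            raise TaxonomyError(f"unknown taxonomy ID {cur}")
        for other in ids[1:]:
            cur = self._lca2(cur, other)
        return cur

    def _lca2(self, a: int, b: int) -> int:
        if b not in self.parents:
            raise TaxonomyError(f"unknown taxonomy ID {b}")
        da, db = self.depth(a), self.depth(b)
        while da > db:
            a = self.parent(a)
            da -= 1
        while db > da:
            b = self.parent(b)
            db -= 1
        while a != b:
            a = self.parent(a)
            b = self.parent(b)
        return a

    def reduce_to_threshold(self, ids, k: int) -> set[int]:
        """Merge IDs to LCAs until at most ``k`` remain.

        The pair whose LCA is deepest merges first (ties to the smaller
        ID pair), preserving as much specificity as possible.
        """
        if k < 1:
            raise ValueError("report threshold must be >= 1")
        current = set(ids)
        for t in current:
            if t not in self.parents:
                raise TaxonomyError(f"unknown taxonomy ID {t}")
        if len(current) <= k:
            return current
        if k == 1:
            return {self.lca(current)}
        while len(current) > k:
            items = sorted(current)
            best = None
            for i in range(len(items)):
                for j in range(i + 1, len(items)):
                    anc = self._lca2(items[i], items[j])
                    key = (-self.depth(anc), items[i], items[j])
                    if best is None or key < best[0]:
                        best = (key, items[i], items[j], anc)
            _, a, b, anc = best
            current -= {a, b}
            current.add(anc)
        return current

    def name(self, taxid: int) -> str:
        return self.names.get(taxid, str(taxid))

    def rank(self, taxid: int) -> str:
        return self.ranks.get(taxid, "no rank")

    def children_map(self) -> dict[int, list[int]]:
        kids: dict[int, list[int]] = {t: [] for t in self.parents}
        for t, p in self.parents.items():
            if t != p:
                kids[p].append(t)
        for v in kids.values():
            v.sort()
        return kids

    # -- serialization -------------------------------------------------
    def state(self) -> dict:
        items = sorted(self.parents)
        return {
            "taxids": items,
            "parents": [self.parents[t] for t in items],
            "ranks": [self.ranks.get(t, "no rank") for t in items],
            "names": [self.names.get(t, "") for t in items],
        }

    @classmethod
    def from_state(cls, state: dict) -> "TaxonomyTree":
        taxids = [int(t) for t in state["taxids"]]
        parents = {t: int(p) for t, p in zip(taxids, state["parents"])}
        ranks = {t: r for t, r in zip(taxids, state["ranks"])}
        names = {t: n for t, n in zip(taxids, state["names"]) if n}
        return cls(parents, ranks, names)


def _parse_dmp_line(line: str, path, lineno: int) -> list[str]:
    line = line.rstrip("\n")
    if line.endswith("\t|"):
        line = line[: -len("\t|")]
    fields = line.split("\t|\t")
    if len(fields) < 2:
        raise TaxonomyError(f"{path}:{lineno}: malformed taxonomy dump line")
    return fields


def parse_taxonomy(nodes_path, names_path=None) -> TaxonomyTree:
    """Parse NCBI-style nodes.dmp (and optionally names.dmp) files."""
    parents: dict[int, int] = {}
    ranks: dict[int, str] = {}
    nodes_path = Path(nodes_path)
    with open(nodes_path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            fields = _parse_dmp_line(line, nodes_path, lineno)
            try:
                taxid, parent = int(fields[0]), int(fields[1])
            except ValueError:
                raise TaxonomyError(
                    f"{nodes_path}:{lineno}: non-integer taxonomy ID"
                ) from None
            parents[taxid] = parent
            ranks[taxid] = fields[2] if len(fields) > 2 else "no rank"
    orphans = {p for p in parents.values() if p not in parents}
    if orphans:
        raise TaxonomyError(f"parent IDs missing from {nodes_path}: {sorted(orphans)}")
    names: dict[int, str] = {}
    if names_path is not None:
        names_path = Path(names_path)
        with open(names_path) as fh:
            for lineno, line in enumerate(fh, 1):
                if not line.strip():
                    continue
                fields = _parse_dmp_line(line, names_path, lineno)
                if len(fields) < 4 or fields[3] != "scientific name":
                    continue
                names[int(fields[0])] = fields[1]
    return TaxonomyTree(parents, ranks, names)


#: Kraken-style single-letter rank codes
RANK_CODES = {
    "superkingdom": "D",
    "domain": "D",
    "kingdom": "K",
    "phylum": "P",
    "class": "C",
    "order": "O",
    "family": "F",
    "genus": "G",
    "species": "S",
    "strain": "S1",
    "subspecies": "S1",
}


def rank_code(rank: str, root: bool = False) -> str:
    if root:
        return "R"
    return RANK_CODES.get(rank, "-")
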