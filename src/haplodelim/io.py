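"""Input/output and shared coordinate conventions.

All the pipeline stages share four containers defined here:

``Alignment``
    an ordered, equal-length nucleotide matrix keyed by sample id;
``SampleTable``
    per-sample metadata (a-priori species label, named clade, in-group flag,
    optional coordinates);
``PhyloTree``
    a rooted, strictly bifurcating tree (a thin wrapper around
    :class:`dendropy.Tree`) whose internal nodes carry support values
    normalised to [0, 1];
``PositionMap``
    a map from alignment columns to the coordinate system of a reference
    sequence (e.g. a complete mitochondrial genome), used to report
    diagnostic positions in reference numbering.

Coordinates are 1-based and closed throughout: positions are reported to
humans, not sliced.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import dendropy
from Bio import SeqIO
from Bio.Align import PairwiseAligner

__all__ = [
    "Alignment",
    "SampleTable",
    "SampleInfo",
    "PhyloTree",
    "PositionMap",
    "AlignmentError",
    "TreeError",
    "SampleTableError",
    "read_alignment",
    "write_alignment",
    "read_tree",
    "write_tree",
    "read_samples",
    "write_samples",
    "map_positions",
]

#: IUPAC nucleotide one-letter codes, their gap, and 'N'.
IUPAC_CODES: Mapping[str, frozenset] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
    "-": frozenset("ACGT"),
}

VALID_CHARS = frozenset(IUPAC_CODES)


class AlignmentError(ValueError):
    """Raised when an alignment violates its invariants."""


class TreeError(ValueError):
    """Raised for unreadable or non-bifurcating trees."""


class SampleTableError(ValueError):
    """Raised for malformed sample metadata tables."""


class Alignment:
    """Equal-length nucleotide sequences keyed by unique sample ids.

    Parameters
    ----------
    records:
        Iterable of ``(sample_id, sequence)`` pairs; order is preserved.
    """

    def __init__(self, records: Iterable[tuple[str, str]]):
        self._records: dict[str, str] = {}
        length = None
        for sid, seq in records:
            if not sid:
                raise AlignmentError("empty sample id")
            if sid in self._records:
                raise AlignmentError(f"duplicate sample id: {sid!r}")
            seq = seq.upper()
            bad = set(seq) - VALID_CHARS
            if bad:
                raise AlignmentError(
                    f"record {sid!r} contains non-IUPAC characters: {sorted(bad)}"
                )
            if length is None:
                length = len(seq)
            elif len(seq) != length:
                raise AlignmentError(
                    f"record {sid!r} has length {len(seq)}, expected {length}"
                )
            self._records[sid] = seq
        if not self._records:
            raise AlignmentError("alignment has no records")
        self.length: int = length

    @property
    def ids(self) -> list[str]:
        return list(self._records)

    @property
    def n(self) -> int:
        return len(self._records)

    def __len__(self) -> int:
        return len(self._records)

    def __getitem__(self, sid: str) -> str:
        return self._records[sid]

    def __contains__(self, sid: str) -> bool:
        return sid in self._records

    def items(self):
        return self._records.items()

    def site(self, pos: int) -> dict[str, str]:
        """Column at 1-based position ``pos`` as ``{sample_id: char}``."""
        if not 1 <= pos <= self.length:
            raise IndexError(f"site {pos} outside [1, {self.length}]")
        return {sid: seq[pos - 1] for sid, seq in self._records.items()}

    def subset(self, ids: Iterable[str]) -> "Alignment":
        """Restrict to ``ids`` (kept in alignment order)."""
        keep = set(ids)
        missing = keep - set(self._records)
        if missing:
            raise AlignmentError(f"ids not in alignment: {sorted(missing)}")
        return Alignment((sid, s) for sid, s in self._records.items() if sid in keep)

    def __eq__(self, other) -> bool:
        return isinstance(other, Alignment) and self._records == other._records


@dataclass
class SampleInfo:
    sample_id: str
    species_label: str
    clade_label: str = "unassigned"
    ingroup: bool = True
    lat: Optional[float] = None
    lon: Optional[float] = None


class SampleTable:
    """Per-sample metadata: a-priori species label, clade, in-group flag."""

    def __init__(self, rows: Iterable[SampleInfo]):
        self._rows: dict[str, SampleInfo] = {}
        for row in rows:
            if not row.sample_id or not row.species_label:
                raise SampleTableError("sample_id and species_label must be non-empty")
            if row.sample_id in self._rows:
                raise SampleTableError(f"duplicate sample id: {row.sample_id!r}")
            self._rows[row.sample_id] = row
        # in-group status must be uniform within a named clade
        by_clade: dict[str, set[bool]] = {}
        for row in self._rows.values():
            by_clade.setdefault(row.clade_label, set()).add(row.ingroup)
        for clade, flags in by_clade.items():
            if len(flags) > 1:
                raise SampleTableError(
                    f"clade {clade!r} mixes in-group and out-group samples"
                )

    def __getitem__(self, sid: str) -> SampleInfo:
        return self._rows[sid]

    def __contains__(self, sid: str) -> bool:
        return sid in self._rows

    def __len__(self) -> int:
        return len(self._rows)

    @property
    def ids(self) -> list[str]:
        return list(self._rows)

    def rows(self) -> list[SampleInfo]:
        return list(self._rows.values())

    def species_labels(self) -> list[str]:
        """Distinct species labels, in first-appearance order."""
        seen: dict[str, None] = {}
        for row in self._rows.values():
            seen.setdefault(row.species_label, None)
        return list(seen)

    def clade_labels(self) -> list[str]:
        seen: dict[str, None] = {}
        for row in self._rows.values():
            seen.setdefault(row.clade_label, None)
        return list(seen)

    def tips_of_species(self, label: str) -> list[str]:
        return [sid for sid, r in self._rows.items() if r.species_label == label]

    def tips_of_clade(self, label: str) -> list[str]:
        return [sid for sid, r in self._rows.items() if r.clade_label == label]

    def ingroup_ids(self) -> list[str]:
        return [sid for sid, r in self._rows.items() if r.ingroup]

    def is_ingroup_species(self, label: str) -> bool:
        return all(self._rows[t].ingroup for t in self.tips_of_species(label))


class PhyloTree:
    """Rooted bifurcating tree with per-node support in [0, 1].

    Wraps a :class:`dendropy.Tree`.  Internal node supports are stored on
    ``node.support`` (``None`` when absent); ``support_scale`` records whether
    the input used posterior probabilities ("probability") or percentages
    ("percent", normalised on read).
    """

    def __init__(self, tree: dendropy.Tree, support_scale: str = "probability"):
        self.tree = tree
        self.support_scale = support_scale
        self._leaf_cache: Optional[dict] = None

    # -- construction ------------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str, allow_polytomies: bool = False) -> "PhyloTree":
        try:
            tree = dendropy.Tree.get(
                data=newick,
                schema="newick",
                suppress_internal_node_taxa=True,
                preserve_underscores=True,
                rooting="force-rooted",
            )
        except Exception as exc:  # dendropy raises various error types
            raise TreeError(f"cannot parse Newick: {exc}") from exc
        leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]
        if len(leaves) != len(set(leaves)):
            raise TreeError("duplicate leaf names in tree")
        # internal labels are supports when numeric
        supports: list[float] = []
        for node in tree.preorder_node_iter():
            if node.is_leaf():
                node.support = None
                continue
            val = None
            if node.label is not None:
                try:
                    val = float(node.label)
                except ValueError:
                    val = None
            node.support = val
            if val is not None:
                supports.append(val)
        scale = "probability"
        if any(v > 1.0 for v in supports):
            scale = "percent"
            for node in tree.preorder_node_iter():
                if getattr(node, "support", None) is not None:
                    node.support = node.support / 100.0
        obj = cls(tree, support_scale=scale)
        obj._enforce_binary(allow_polytomies)
        return obj

    def _enforce_binary(self, allow_polytomies: bool) -> None:
        for node in list(self.tree.preorder_node_iter()):
            kids = node.child_nodes()
            if len(kids) <= 2:
                continue
            if not allow_polytomies:
                raise TreeError(
                    f"polytomy with {len(kids)} children at node "
                    f"{node.label or '<unnamed>'}; pass allow_polytomies=True "
                    "for deterministic left-branching resolution"
                )
            # deterministic left-branching resolution in input order
            while len(node.child_nodes()) > 2:
                kids = node.child_nodes()
                a, b = kids[0], kids[1]
                node.remove_child(a)
                node.remove_child(b)
                new = dendropy.Node()
                new.support = None
                new.add_child(a)
                new.add_child(b)
                node.insert_child(0, new)
        self._leaf_cache = None

    # -- queries -----------------------------------------------------------

    @property
    def leaf_names(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    def _leaves_under(self) -> dict:
        """Cache node -> frozenset of descendant leaf names."""
        if self._leaf_cache is None:
            cache = {}
            for node in self.tree.postorder_node_iter():
                if node.is_leaf():
                    cache[node] = frozenset([node.taxon.label])
                else:
                    s = frozenset()
                    for ch in node.child_nodes():
                        s |= cache[ch]
                    cache[node] = s
            self._leaf_cache = cache
        return self._leaf_cache

    def mrca(self, tips: Iterable[str]):
        """Most recent common ancestor node of the named tips."""
        tips = frozenset(tips)
        missing = tips - set(self.leaf_names)
        if missing:
            raise TreeError(f"tips not in tree: {sorted(missing)}")
        cache = self._leaves_under()
        best = self.tree.seed_node
        # smallest node whose leaf set covers tips
        for node in self.tree.postorder_node_iter():
            if tips <= cache[node] and len(cache[node]) < len(cache[best]):
                best = node
        return best

    def leaves_under(self, node) -> frozenset:
        return self._leaves_under()[node]

    def support_of(self, node) -> Optional[float]:
        return getattr(node, "support", None)

    def sister_of(self, node):
        """Sibling node, or None at the root."""
        parent = node.parent_node
        if parent is None:
            return None
        for ch in parent.child_nodes():
            if ch is not node:
                return ch
        return None

    def as_newick(self) -> str:
        tree = self.tree.clone(depth=1)
        for node in tree.preorder_node_iter():
            if not node.is_leaf():
                sup = getattr(node, "support", None)
                node.label = None if sup is None else format(sup, "g")
        return tree.as_string(schema="newick", suppress_rooting=True).strip()


@dataclass
class PositionMap:
    """Map from alignment sites (1-based) to reference coordinates (1-based).

    Sites opposite a reference gap carry ``None`` and are reported by
    alignment coordinate with an ``aln:`` prefix.
    """

    reference_name: str
    mapping: dict = field(default_factory=dict)  # site -> int | None

    def label(self, site: int) -> str:
        ref = self.mapping.get(site)
        return f"aln:{site}" if ref is None else str(ref)


# ---------------------------------------------------------------------------
# readers / writers


def read_alignment(path, format: str = "fasta") -> Alignment:
    """Read an aligned FASTA file into an :class:`Alignment`.

    Record order follows file order.  Ragged lengths, duplicate ids and empty
    files raise :class:`AlignmentError` naming the offending record.
    """
    if format != "fasta":
        raise ValueError(f"unsupported alignment format: {format}")
    records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    return Alignment(records)


def write_alignment(alignment: Alignment, path) -> None:
    with open(path, "w") as fh:
        for sid, seq in alignment.items():
            fh.write(f">{sid}\n{seq}\n")


def read_tree(path, allow_polytomies: bool = False) -> PhyloTree:
    """Read a rooted Newick tree with numeric internal labels as supports.

    A support value above 1 anywhere marks the file as percent-scaled and all
    supports are divided by 100.
    """
    with open(path) as fh:
        text = fh.read()
    if not text.strip():
        raise TreeError(f"empty tree file: {path}")
    return PhyloTree.from_newick(text, allow_polytomies=allow_polytomies)


def write_tree(tree: PhyloTree, path) -> None:
    with open(path, "w") as fh:
        fh.write(tree.as_newick() + "\n")


_TRUE = {"1", "true", "yes", "t"}
_FALSE = {"0", "false", "no", "f"}


def read_samples(path) -> SampleTable:
    """Read a TSV metadata table (sample_id, species_label[, clade_label,
    ingroup, lat, lon]) into a :class:`SampleTable`."""
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise SampleTableError(f"empty sample table: {path}")
    header = lines[0].split("\t")
    for req in ("sample_id", "species_label"):
        if req not in header:
            raise SampleTableError(f"missing required column {req!r}")
    idx = {name: i for i, name in enumerate(header)}
    rows = []
    for ln in lines[1:]:
        parts = ln.split("\t")

        def get(col, default=None):
            i = idx.get(col)
            if i is None or i >= len(parts) or parts[i] == "":
                return default
            return parts[i]

        ing_raw = get("ingroup", "true").strip().lower()
        if ing_raw in _TRUE:
            ingroup = True
        elif ing_raw in _FALSE:
            ingroup = False
        else:
            raise SampleTableError(f"unparseable ingroup flag: {ing_raw!r}")
        lat, lon = get("lat"), get("lon")
        rows.append(
            SampleInfo(
                sample_id=get("sample_id", ""),
                species_label=get("species_label", ""),
                clade_label=get("clade_label", "unassigned"),
                ingroup=ingroup,
                lat=float(lat) if lat is not None else None,
                lon=float(lon) if lon is not None else None,
            )
        )
    return SampleTable(rows)


def write_samples(table: SampleTable, path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tspecies_label\tclade_label\tingroup\tlat\tlon\n")
        for r in table.rows():
            lat = "" if r.lat is None else repr(r.lat)
            lon = "" if r.lon is None else repr(r.lon)
            fh.write(
                f"{r.sample_id}\t{r.species_label}\t{r.clade_label}\t"
                f"{'true' if r.ingroup else 'false'}\t{lat}\t{lon}\n"
            )


# ---------------------------------------------------------------------------
# reference position mapping

#: Fixed global-alignment scores for reference mapping (match, mismatch, gap).
MAP_SCORES = (1.0, -1.0, -2.0)


def _consensus(alignment: Alignment) -> str:
    """Majority-rule consensus ignoring gaps/N; ties broken alphabetically."""
    cols = []
    seqs = [s for _, s in alignment.items()]
    for j in range(alignment.length):
        counts: dict[str, int] = {}
        for s in seqs:
            c = s[j]
            if c in "ACGT":
                counts[c] = counts.get(c, 0) + 1
        if counts:
            cols.append(min(sorted(counts), key=lambda c: (-counts[c], c)))
        else:
            cols.append("N")
    return "".join(cols)


def map_positions(alignment: Alignment, reference: str, reference_name: str = "reference") -> PositionMap:
    """Number alignment columns in the coordinates of ``reference``.

    The alignment's majority consensus is globally aligned to the reference
    (match +1, mismatch −1, gap −2, linear); each consensus column paired with
    a reference base maps to that base's 1-based position, columns opposite
    reference gaps stay unnumbered.
    """
    reference = reference.upper().replace("-", "")
    if not reference:
        raise ValueError("empty reference sequence")
    if len(reference) < alignment.length / 2:
        warnings.warn(
            "reference is shorter than half the alignment; position numbering "
            "may be mostly undefined",
            stacklevel=2,
        )
    cons = _consensus(alignment)

    aligner = PairwiseAligner()
    aligner.mode = "global"
    match, mismatch, gap = MAP_SCORES
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap
    aligner.extend_gap_score = gap
    aln = aligner.align(reference, cons)[0]

    mapping: dict[int, Optional[int]] = {site: None for site in range(1, alignment.length + 1)}
    n_paired = n_ident = 0
    for (r0, r1), (c0, c1) in zip(*aln.aligned):
        for k in range(r1 - r0):
            site = c0 + k + 1
            refpos = r0 + k + 1
            mapping[site] = refpos
            n_paired += 1
            if reference[refpos - 1] == cons[site - 1]:
                n_ident += 1
    if n_paired == 0 or n_ident / n_paired < 0.3:
        raise ValueError(
            "reference is unalignable to the alignment consensus "
            f"({n_ident}/{n_paired} identities)"
        )
    return PositionMap(reference_name=reference_name, mapping=mapping)
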