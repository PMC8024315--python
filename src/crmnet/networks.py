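"""Network containers shared across construction, consensus, and annotation.

A regulatory network is a bag of TF-CRM-TG triplets: a directed TF -> TG
edge carrying a non-negative regulatory strength and a cis-regulatory
module (CRM), the sorted, merged set of regulatory-element intervals
through which the TF is predicted to act on the TG.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

from .io import GenomicInterval, ParseError, merge_intervals, parse_region


@dataclass(frozen=True)
class Triplet:
    """One TF-CRM-TG regulation: directed edge plus its CRM intervals."""

    tf: str
    tg: str
    score: float
    crm: tuple[GenomicInterval, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "crm", tuple(merge_intervals(self.crm)))

    @property
    def edge(self) -> tuple[str, str]:
        return (self.tf, self.tg)


@dataclass
class SolverDiagnostics:
    iterations: int = 0
    max_delta_s: float = float("inf")
    max_delta_c: float = float("inf")
    converged: bool = False


class _TripletNetwork:
    def __init__(self, triplets: Iterable[Triplet] = ()):
        self.triplets: dict[tuple[str, str], Triplet] = {}
        for t in triplets:
            if t.edge in self.triplets:
                raise ValueError(f"duplicate triplet for edge {t.edge}")
            self.triplets[t.edge] = t

    def __len__(self) -> int:
        return len(self.triplets)

    def __iter__(self):
        return iter(sorted(self.triplets.values(), key=lambda t: t.edge))

    def __contains__(self, edge: tuple[str, str]) -> bool:
        return edge in self.triplets

    def __getitem__(self, edge: tuple[str, str]) -> Triplet:
        return self.triplets[edge]

    def edges(self) -> set[tuple[str, str]]:
        return set(self.triplets)

    @property
    def tfs(self) -> list[str]:
        return sorted({t.tf for t in self.triplets.values()})

    @property
    def tgs(self) -> list[str]:
        return sorted({t.tg for t in self.triplets.values()})


class ReplicateNetwork(_TripletNetwork):
    """One replicate's context-specific network (S^r, C^r)."""

    def __init__(
        self,
        replicate_id: str,
        triplets: Iterable[Triplet] = (),
        weight: float = 1.0,
        n_tfs: int | None = None,
        n_tgs: int | None = None,
    ):
        super().__init__(triplets)
        if weight <= 0:
            raise ValueError("replicate weight must be > 0")
        for t in self.triplets.values():
            if t.score <= 0:
                raise ValueError(
                    f"replicate {replicate_id}: stored triplet {t.edge} has "
                    f"non-positive score {t.score}"
                )
        self.replicate_id = replicate_id
        self.weight = float(weight)
        self.n_tfs = n_tfs if n_tfs is not None else len(self.tfs)
        self.n_tgs = n_tgs if n_tgs is not None else len(self.tgs)


class ConsensusNetwork(_TripletNetwork):
    """Integrated network with consensus strengths and binarized CRMs.

    ``relaxed`` optionally carries the solver's per-pair relaxed CRM
    vectors (values in [0, 1]) keyed by edge; :func:`crmnet.consensus.
    finalize_network` consumes them to produce binary CRM intervals.
    """

    def __init__(
        self,
        triplets: Iterable[Triplet] = (),
        diagnostics: SolverDiagnostics | None = None,
        relaxed: Mapping[tuple[str, str], object] | None = None,
    ):
        super().__init__(triplets)
        for t in self.triplets.values():
            if t.score < 0:
                raise ValueError(f"triplet {t.edge} has negative score {t.score}")
        self.diagnostics = diagnostics or SolverDiagnostics()
        self.relaxed = dict(relaxed) if relaxed else {}

    # -- triplet TSV serialization -----------------------------------------

    HEADER = "tf\ttg\tscore\tcrm"

    def write_tsv(self, path: str | Path, header_lines: Iterable[str] = ()) -> None:
        with open(path, "w", encoding="utf-8") as handle:
            for line in header_lines:
                handle.write(f"# {line}\n")
            handle.write(self.HEADER + "\n")
            for t in self:
                crm = ";".join(iv.region_string() for iv in t.crm)
                handle.write(f"{t.tf}\t{t.tg}\t{t.score:.6g}\t{crm}\n")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "ConsensusNetwork":
        triplets: list[Triplet] = []
        with open(path, encoding="utf-8") as handle:
            header_seen = False
            for lineno, raw in enumerate(handle, start=1):
                line = raw.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                if not header_seen:
                    if line != cls.HEADER:
                        raise ParseError(f"{path}:{lineno}: unexpected header {line!r}")
                    header_seen = True
                    continue
                fields = line.split("\t")
                if len(fields) != 4:
                    raise ParseError(f"{path}:{lineno}: expected 4 fields")
                crm = tuple(
                    parse_region(r) for r in fields[3].split(";") if r
                )
                triplets.append(Triplet(fields[0], fields[1], float(fields[2]), crm))
        if not header_seen:
            raise ParseError(f"{path}: missing header line")
        return cls(triplets)

    def to_edge_list(self):
        from .io import EdgeList

        weights = {t.edge: t.score for t in self.triplets.values()}
        return EdgeList(self.edges(), weights, allow_self_loops=True)
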