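"""Degenerate probe-panel design for tRNA microarrays.

Each probe is the reverse complement of a 3'-anchored window of the mature
tRNA body (terminal CCA excluded). Species whose windows differ by fewer
residues than hybridization can discriminate are pooled under one probe whose
sequence carries IUPAC ambiguity codes at the divergent columns, so a single
spot captures a whole isodecoder group. The panel is audited for residual
cross-hybridization, and per-probe GC content and melting temperature are
reported so panel uniformity can be checked.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd
from Bio.Data.IUPACData import ambiguous_dna_values
from Bio.Seq import Seq

from .catalog import TrnaCatalog, TrnaSpecies

__all__ = [
    "DesignParams",
    "Probe",
    "ProbeSet",
    "probe_window",
    "window_mismatch",
    "cluster_species",
    "degenerate_consensus",
    "compute_gc",
    "compute_tm",
    "cross_check",
    "design",
    "write_probe_table",
    "read_probe_table",
]

#: IUPAC code <-> set of bases (X, a legacy alias of N, excluded)
_IUPAC_TO_SET = {
    code: frozenset(bases)
    for code, bases in ambiguous_dna_values.items()
    if code != "X"
}
_SET_TO_IUPAC = {bases: code for code, bases in _IUPAC_TO_SET.items()}
#: gap symbol used to pad shorter windows at the 5' side; fully degenerate
GAP = "-"


@dataclass(frozen=True)
class DesignParams:
    """Panel-design parameters.

    window_length
        Probe length in nt; the probe covers the 3'-most ``window_length``
        residues of the CCA-less tRNA body.
    mismatch_threshold
        Number of residue differences hybridization can discriminate.
        Species pairs differing by *fewer* residues are merged under one
        degenerate probe; pairs at or above it get separate probes.
    exclude_terminal_cca
        Drop a terminal CCA from the body before windowing (the CCA is
        shared by all tRNAs and carries no discriminating information).
    sodium_molarity
        Monovalent cation concentration (mol/L) for the Tm salt correction;
        0.3 M corresponds to the NaCl of 2X SSC hybridization buffer.
    """

    window_length: int = 70
    mismatch_threshold: int = 8
    exclude_terminal_cca: bool = True
    sodium_molarity: float = 0.3

    def __post_init__(self) -> None:
        if self.window_length < 1:
            raise ValueError("window_length must be >= 1")
        if self.mismatch_threshold < 1:
            raise ValueError("mismatch_threshold must be >= 1")
        if self.sodium_molarity <= 0:
            raise ValueError("sodium_molarity must be > 0")


@dataclass(frozen=True)
class Probe:
    """A (possibly degenerate) DNA probe, 5'->3', reverse complement of the
    consensus target window."""

    probe_id: str
    sequence: str
    targets: tuple[str, ...]
    degenerate_positions: int
    gc_percent: float
    tm_celsius: float


@dataclass
class ProbeSet:
    probes: list[Probe]
    params: DesignParams
    audit: pd.DataFrame | None = None

    def by_id(self) -> dict[str, Probe]:
        return {p.probe_id: p for p in self.probes}

    def targets_of(self, probe_id: str) -> tuple[str, ...]:
        return self.by_id()[probe_id].targets


def probe_window(species: TrnaSpecies | str, params: DesignParams) -> str:
    """3'-anchored target window: the last ``window_length`` residues of the
    CCA-less body (the whole body when it is shorter)."""
    if isinstance(species, TrnaSpecies):
        body = species.sequence  # catalog stores CCA-less bodies
    else:
        body = species
        if params.exclude_terminal_cca and body.endswith("CCA"):
            body = body[:-3]
    if not body:
        raise ValueError("empty tRNA body")
    return body[-params.window_length:]


def window_mismatch(a: str, b: str) -> int:
    """Residue differences between two windows under 3'-anchored alignment.

    Windows are aligned at their 3' ends; each unpaired 5' residue of the
    longer window counts as one mismatch. Symmetric, zero iff identical.
    """
    if not a or not b:
        raise ValueError("windows must be non-empty")
    ra, rb = a[::-1], b[::-1]
    n = min(len(ra), len(rb))
    mism = sum(1 for x, y in zip(ra[:n], rb[:n]) if x != y)
    return mism + abs(len(a) - len(b))


def cluster_species(
    windows: dict[str, str], threshold: int
) -> list[list[str]]:
    """Single-linkage clusters joining pairs with mismatch < ``threshold``.

    Any chain of pairwise-similar windows shares a cluster (and hence a
    probe). Members are sorted by species_id; clusters by first member.
    """
    ids = sorted(windows)
    if not ids:
        raise ValueError("no windows to cluster")
    parent = {i: i for i in ids}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            if window_mismatch(windows[a], windows[b]) < threshold:
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[max(ra, rb)] = min(ra, rb)

    groups: dict[str, list[str]] = {}
    for x in ids:
        groups.setdefault(find(x), []).append(x)
    return [sorted(groups[root]) for root in sorted(groups)]


def degenerate_consensus(windows: list[str]) -> tuple[str, int]:
    """IUPAC consensus of a cluster's windows and its degenerate-column count.

    Shorter windows are padded at the 5' side with a gap treated as fully
    degenerate (N). Returns the consensus of the *target* windows (sense
    strand); the probe is its reverse complement.
    """
    if not windows:
        raise ValueError("no windows")
    width = max(len(w) for w in windows)
    padded = [w.rjust(width, GAP) for w in windows]
    cols = []
    for j in range(width):
        observed: set[str] = set()
        for w in padded:
            c = w[j]
            if c == GAP:
                observed |= set("ACGT")
            elif c in "ACGT":
                observed.add(c)
            else:
                raise ValueError(f"non-DNA symbol {c!r} in window")
        cols.append(_SET_TO_IUPAC[frozenset(observed)])
    consensus = "".join(cols)
    n_degenerate = sum(1 for c in consensus if c not in "ACGT")
    return consensus, n_degenerate


def _gc_fraction(code: str) -> float:
    try:
        bases = _IUPAC_TO_SET[code]
    except KeyError:
        raise ValueError(f"invalid IUPAC symbol {code!r}") from None
    return sum(1 for b in bases if b in "GC") / len(bases)


def compute_gc(sequence: str) -> float:
    """Expected GC percentage; ambiguity codes contribute their expected
    G+C fraction under a uniform choice among their bases (W=0, S=1, N=0.5)."""
    if not sequence:
        raise ValueError("empty sequence")
    return 100.0 * sum(_gc_fraction(c) for c in sequence.upper()) / len(sequence)


def compute_tm(sequence: str, sodium_molarity: float = 0.3) -> float:
    """Salt-adjusted Marmur-Schildkraut-Doty melting temperature (degC).

    Tm = 81.5 + 16.6*log10([Na+]) + 0.41*GC% - 675/N. Composition-only;
    valid for oligos of ~14 nt and longer.
    """
    if sodium_molarity <= 0:
        raise ValueError("sodium_molarity must be > 0")
    n = len(sequence)
    if n < 14:
        raise ValueError("Tm formula requires length >= 14")
    gc = compute_gc(sequence)
    return 81.5 + 16.6 * math.log10(sodium_molarity) + 0.41 * gc - 675.0 / n


def cross_check(
    probe_set: ProbeSet, catalog: TrnaCatalog, params: DesignParams
) -> pd.DataFrame:
    """Audit every probe against every non-target species.

    Returns one row per (probe, non-target species) with the window mismatch
    count; rows with count < threshold are flagged as cross-hybridization
    risks.
    """
    windows = {
        sp.species_id: probe_window(sp, params) for sp in catalog.species
    }
    rows = []
    for probe in probe_set.probes:
        # compare against the probe's own consensus target window
        target_window = str(Seq(probe.sequence).reverse_complement())
        for sid in sorted(windows):
            if sid in probe.targets:
                continue
            mm = _degenerate_mismatch(target_window, windows[sid])
            rows.append(
                {
                    "probe_id": probe.probe_id,
                    "species_id": sid,
                    "mismatches": mm,
                    "flagged": mm < params.mismatch_threshold,
                }
            )
    return pd.DataFrame(
        rows, columns=["probe_id", "species_id", "mismatches", "flagged"]
    )


def _degenerate_mismatch(consensus: str, window: str) -> int:
    """3'-anchored mismatches counting a column as matched when the window
    base is compatible with the consensus IUPAC code."""
    ra, rb = consensus[::-1], window[::-1]
    n = min(len(ra), len(rb))
    mism = 0
    for x, y in zip(ra[:n], rb[:n]):
        if y not in _IUPAC_TO_SET.get(x, frozenset()):
            mism += 1
    return mism + abs(len(consensus) - len(window))


def _probe_id(
    targets: list[str], catalog_species: dict[str, TrnaSpecies],
    used: dict[str, int],
) -> str:
    names = sorted(
        {
            f"{catalog_species[t].amino_acid}-{catalog_species[t].anticodon}"
            for t in targets
        }
    )
    base = "+".join(names)
    used[base] = used.get(base, 0) + 1
    return base if used[base] == 1 else f"{base}.{used[base]}"


def design(catalog: TrnaCatalog, params: DesignParams | None = None) -> ProbeSet:
    """Design the minimal degenerate probe panel for a catalog.

    Pipeline: 3' windows -> single-linkage clustering at the discrimination
    threshold -> IUPAC consensus per cluster -> reverse complement ->
    GC/Tm -> cross-hybridization audit. Deterministic for a fixed catalog.
    """
    params = params or DesignParams()
    if not catalog.species:
        raise ValueError("empty catalog")
    species_by_id = catalog.species_by_id()
    windows = {
        sp.species_id: probe_window(sp, params) for sp in catalog.species
    }
    clusters = cluster_species(windows, params.mismatch_threshold)
    probes: list[Probe] = []
    used: dict[str, int] = {}
    for members in clusters:
        consensus, _ = degenerate_consensus([windows[m] for m in members])
        probe_seq = str(Seq(consensus).reverse_complement())
        n_degenerate = sum(1 for c in probe_seq if c not in "ACGT")
        probes.append(
            Probe(
                probe_id=_probe_id(members, species_by_id, used),
                sequence=probe_seq,
                targets=tuple(members),
                degenerate_positions=n_degenerate,
                gc_percent=compute_gc(probe_seq),
                tm_celsius=compute_tm(probe_seq, params.sodium_molarity),
            )
        )
    probe_set = ProbeSet(probes=probes, params=params)
    probe_set.audit = cross_check(probe_set, catalog, params)
    return probe_set


_PROBE_COLUMNS = [
    "probe_id", "sequence", "targets", "degenerate_positions",
    "gc_percent", "tm_celsius",
]


def write_probe_table(probe_set: ProbeSet, path) -> None:
    """Write the panel as TSV (targets comma-joined, GC/Tm to 2 decimals)."""
    with open(path, "w") as fh:
        fh.write("\t".join(_PROBE_COLUMNS) + "\n")
        for p in probe_set.probes:
            fh.write(
                f"{p.probe_id}\t{p.sequence}\t{','.join(p.targets)}\t"
                f"{p.degenerate_positions}\t{p.gc_percent:.2f}\t"
                f"{p.tm_celsius:.2f}\n"
            )


def read_probe_table(path, params: DesignParams | None = None) -> ProbeSet:
    """Read a probe table TSV written by :func:`write_probe_table`."""
    probes: list[Probe] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _PROBE_COLUMNS:
            raise ValueError(f"{path}: unexpected probe-table header {header}")
        for lineno, line in enumerate(fh, 2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(_PROBE_COLUMNS):
                raise ValueError(f"{path}:{lineno}: malformed row")
            pid, seq, targets, ndeg, gc, tm = parts
            probes.append(
                Probe(
                    probe_id=pid, sequence=seq,
                    targets=tuple(targets.split(",")),
                    degenerate_positions=int(ndeg),
                    gc_percent=float(gc), tm_celsius=float(tm),
                )
            )
    return ProbeSet(probes=probes, params=params or DesignParams())
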