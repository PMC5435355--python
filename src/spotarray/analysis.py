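"""Downstream analytics on tRNA array profiles.

Covers replicate statistics across biological-replicate arrays, size-class
fractions, fold change between conditions, copy-number and operon views of
expression, and the correlation of measured tRNA levels with codon usage
made wobble-aware: each tRNA is credited with the genomic frequency of every
codon it can decode (Watson-Crick pairing at codon positions 1-2 against
anticodon positions 36 and 35, wobble rules at position 3 against anticodon
position 34), with codons decoded by several species split equally among
them so total usage mass is conserved.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .catalog import TrnaCatalog
from .probes import ProbeSet
from .quantify import TrnaProfile

__all__ = [
    "ReplicateStats",
    "DecodingRules",
    "CorrelationResult",
    "replicate_stats",
    "class_fractions",
    "fold_change",
    "copy_group_medians",
    "per_copy_levels",
    "group_mean_per_copy",
    "effective_codon_frequency",
    "correlate",
    "codon_usage_correlation",
    "read_codon_usage_tsv",
    "STOP_CODONS",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
SENSE_CODONS = tuple(
    sorted(
        a + b + c
        for a in "ACGT" for b in "ACGT" for c in "ACGT"
        if a + b + c not in STOP_CODONS
    )
)

#: Crick wobble set: anticodon position 34 -> codon third bases it reads
#: (DNA alphabet; A at 34 treated as inosine, reading U, C and A).
DEFAULT_WOBBLE = {
    "G": frozenset({"C", "T"}),
    "C": frozenset({"G"}),
    "T": frozenset({"A", "G"}),
    "A": frozenset({"T", "C", "A"}),
}


@dataclass
class ReplicateStats:
    """Per-probe statistics across replicate arrays plus panel medians."""

    table: pd.DataFrame  # index probe_id; median, sd, cv_percent
    panel_median_level: float
    panel_median_sd: float
    panel_median_cv: float


@dataclass(frozen=True)
class DecodingRules:
    """Wobble table plus optional per-anticodon overrides of the full
    readable codon set."""

    wobble: dict[str, frozenset[str]] = field(
        default_factory=lambda: dict(DEFAULT_WOBBLE)
    )
    overrides: dict[str, frozenset[str]] = field(default_factory=dict)

    def decoded_codons(self, anticodon: str) -> tuple[str, ...]:
        """Sense codons readable by an anticodon (5'->3', DNA)."""
        if anticodon in self.overrides:
            codons = self.overrides[anticodon]
        else:
            c1 = anticodon[2].translate(_COMPLEMENT)
            c2 = anticodon[1].translate(_COMPLEMENT)
            thirds = self.wobble[anticodon[0]]
            codons = {c1 + c2 + t for t in thirds}
        return tuple(sorted(c for c in codons if c not in STOP_CODONS))


@dataclass(frozen=True)
class CorrelationResult:
    r_squared: float
    n: int
    excluded: tuple[str, ...] = ()


def _levels_frame(profiles: list[TrnaProfile]) -> pd.DataFrame:
    panels = [tuple(sorted(p.level)) for p in profiles]
    if len(set(panels)) != 1:
        raise ValueError("profiles do not share one probe panel")
    return pd.DataFrame([p.level for p in profiles])


def replicate_stats(profiles: list[TrnaProfile]) -> ReplicateStats:
    """Per-probe median, SD and CV% of percent levels across >= 2 arrays.

    The CV (coefficient of variation, 100*SD/mean) is the per-probe "false
    change" a replicate experiment would see without any biology.
    """
    if len(profiles) < 2:
        raise ValueError("need at least two replicate profiles")
    frame = _levels_frame(profiles)
    med = frame.median(axis=0)
    sd = frame.std(axis=0, ddof=1)
    mean = frame.mean(axis=0)
    cv = 100.0 * sd / mean
    table = pd.DataFrame(
        {"median": med, "sd": sd, "cv_percent": cv}
    ).sort_index()
    return ReplicateStats(
        table=table,
        panel_median_level=float(med.median()),
        panel_median_sd=float(sd.median()),
        panel_median_cv=float(cv.median()),
    )


def _probe_class(
    probe_id: str, probe_set: ProbeSet, catalog: TrnaCatalog
) -> str:
    species = catalog.species_by_id()
    classes = {
        species[sid].size_class for sid in probe_set.targets_of(probe_id)
    }
    if len(classes) != 1:
        raise ValueError(f"probe {probe_id} targets span both size classes")
    return classes.pop()


def class_fractions(
    profile: TrnaProfile, catalog: TrnaCatalog, probe_set: ProbeSet
) -> dict[str, float]:
    """Percent of total signal carried by class I vs class II tRNAs."""
    out = {"I": 0.0, "II": 0.0}
    for pid, level in profile.level.items():
        out[_probe_class(pid, probe_set, catalog)] += level
    return out


def fold_change(
    profile: TrnaProfile, control: TrnaProfile
) -> dict[str, float]:
    """Per-probe ratio of percent levels vs a control array.

    Probes with zero control level get NaN (undefined), never infinity.
    """
    if sorted(profile.level) != sorted(control.level):
        raise ValueError("profiles do not share one probe panel")
    out: dict[str, float] = {}
    for pid, level in profile.level.items():
        c = control.level[pid]
        out[pid] = level / c if c > 0 else float("nan")
    return out


def _probe_copies(
    probe_id: str, probe_set: ProbeSet, catalog: TrnaCatalog
) -> int:
    species = catalog.species_by_id()
    return sum(
        species[sid].gene_copies for sid in probe_set.targets_of(probe_id)
    )


def copy_group_medians(
    profile: TrnaProfile, catalog: TrnaCatalog, probe_set: ProbeSet
) -> dict[int, float]:
    """Median percent level per gene-copy-number group (probes grouped by the
    total gene copies of their targets)."""
    groups: dict[int, list[float]] = {}
    for pid, level in profile.level.items():
        groups.setdefault(_probe_copies(pid, probe_set, catalog), []).append(level)
    return {k: float(np.median(v)) for k, v in sorted(groups.items())}


def per_copy_levels(
    profile: TrnaProfile, catalog: TrnaCatalog, probe_set: ProbeSet
) -> pd.DataFrame:
    """Per-probe level divided by target gene copies; when gene loci are
    available the rows carry locus midpoints and are ordered along the
    chromosome."""
    species = catalog.species_by_id()
    gene_by_body: dict[str, list] = {}
    for g in catalog.genes:
        body = g.sequence[:-3] if g.sequence.endswith("CCA") else g.sequence
        gene_by_body.setdefault(body, []).append(g)
    rows = []
    for pid, level in profile.level.items():
        copies = _probe_copies(pid, probe_set, catalog)
        mids = []
        for sid in probe_set.targets_of(pid):
            for g in gene_by_body.get(species[sid].sequence, []):
                if g.locus is not None:
                    mids.append((g.locus[1] + g.locus[2]) / 2)
        rows.append(
            {
                "probe_id": pid,
                "level_percent": level,
                "gene_copies": copies,
                "level_per_copy": level / copies,
                "locus_midpoint": float(np.mean(mids)) if mids else np.nan,
            }
        )
    frame = pd.DataFrame(rows)
    if frame["locus_midpoint"].notna().any():
        frame = frame.sort_values(
            "locus_midpoint", kind="mergesort", na_position="last"
        ).reset_index(drop=True)
    return frame


def group_mean_per_copy(
    profile: TrnaProfile,
    catalog: TrnaCatalog,
    probe_set: ProbeSet,
    operon_labels: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Mean +/- SD of per-copy levels by operon-annotation group.

    ``operon_labels`` maps gene_id -> group label (defaults to the catalog's
    own annotation); genes without a label fall into "other". A probe joins
    every group that annotates at least one of its target genes.
    """
    labels = operon_labels if operon_labels is not None else catalog.operon_annotation
    species = catalog.species_by_id()
    gene_label: dict[str, str] = {
        g.gene_id: labels.get(g.gene_id, "other") for g in catalog.genes
    }
    gene_by_body: dict[str, list] = {}
    for g in catalog.genes:
        body = g.sequence[:-3] if g.sequence.endswith("CCA") else g.sequence
        gene_by_body.setdefault(body, []).append(g)
    per_group: dict[str, list[float]] = {}
    for pid, level in profile.level.items():
        copies = _probe_copies(pid, probe_set, catalog)
        value = level / copies
        groups = set()
        for sid in probe_set.targets_of(pid):
            for g in gene_by_body.get(species[sid].sequence, []):
                groups.add(gene_label[g.gene_id])
        for grp in groups or {"other"}:
            per_group.setdefault(grp, []).append(value)
    rows = [
        {
            "group": grp,
            "n": len(vals),
            "mean_per_copy": float(np.mean(vals)),
            "sd_per_copy": float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0,
        }
        for grp, vals in sorted(per_group.items())
    ]
    return pd.DataFrame(rows)


def effective_codon_frequency(
    codon_usage: dict[str, float],
    catalog: TrnaCatalog,
    rules: DecodingRules | None = None,
    split: str = "equal",
) -> dict[str, float]:
    """Wobble-aware effective decoded codon frequency per tRNA species.

    f(t) = sum over codons c decodable by t of usage(c)/n(c), where n(c) is
    the number of catalog species decoding c ("equal" split; conserves total
    usage over decoded codons). ``split="winner"`` instead credits each codon
    entirely to every decoder (sensitivity mode; not mass-conserving).
    Codons decoded by no species are reported in a warning.
    """
    rules = rules or DecodingRules()
    if split not in ("equal", "winner"):
        raise ValueError("split must be 'equal' or 'winner'")
    missing = [c for c in SENSE_CODONS if c not in codon_usage]
    if missing:
        raise ValueError(f"codon usage table lacks sense codons: {missing[:5]}")
    decoders: dict[str, list[str]] = {c: [] for c in SENSE_CODONS}
    decoded_by: dict[str, tuple[str, ...]] = {}
    for sp in catalog.species:
        codons = rules.decoded_codons(sp.anticodon)
        decoded_by[sp.species_id] = codons
        for c in codons:
            decoders[c].append(sp.species_id)
    orphans = [c for c, ts in decoders.items() if not ts and codon_usage[c] > 0]
    if orphans:
        warnings.warn(
            f"{len(orphans)} used sense codons decoded by no species: "
            f"{orphans}",
            stacklevel=2,
        )
    freq: dict[str, float] = {}
    for sp in catalog.species:
        total = 0.0
        for c in decoded_by[sp.species_id]:
            n = len(decoders[c])
            total += codon_usage[c] / n if split == "equal" else codon_usage[c]
        freq[sp.species_id] = total
    return freq


def correlate(
    x: dict[str, float],
    y: dict[str, float],
    exclude: tuple[str, ...] = (),
) -> CorrelationResult:
    """Squared Pearson correlation over the shared keys of two maps.

    ``exclude`` removes keys before correlating. Raises when fewer than 3
    points remain or either vector has zero variance.
    """
    keys = sorted((set(x) & set(y)) - set(exclude))
    if len(keys) < 3:
        raise ValueError("need at least 3 shared points")
    xv = np.array([x[k] for k in keys])
    yv = np.array([y[k] for k in keys])
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        raise ValueError("zero variance in correlation input")
    r, _ = stats.pearsonr(xv, yv)
    return CorrelationResult(
        r_squared=float(r**2), n=len(keys), excluded=tuple(exclude)
    )


def codon_usage_correlation(
    profile: TrnaProfile,
    catalog: TrnaCatalog,
    probe_set: ProbeSet,
    codon_usage: dict[str, float],
    rules: DecodingRules | None = None,
    exclude: str | tuple[str, ...] = "auto",
) -> CorrelationResult:
    """Correlate measured per-probe levels with wobble-aware codon frequency.

    Per-probe effective frequency is the sum of f(t) over the probe's target
    species. ``exclude="auto"`` drops probes targeting selenocysteine tRNA,
    whose UGA codon is recoded only in specific mRNA contexts; pass a tuple
    of probe ids (possibly empty) to override.
    """
    freq = effective_codon_frequency(codon_usage, catalog, rules)
    species = catalog.species_by_id()
    probe_freq = {
        p.probe_id: sum(freq[sid] for sid in p.targets)
        for p in probe_set.probes
    }
    if exclude == "auto":
        exclude = tuple(
            p.probe_id
            for p in probe_set.probes
            if any(species[sid].amino_acid == "SeC" for sid in p.targets)
        )
    return correlate(profile.level, probe_freq, exclude=tuple(exclude))


def read_codon_usage_tsv(path) -> dict[str, float]:
    """Read a two-column (codon, frequency) TSV; accepts U or T codons."""
    usage: dict[str, float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#") or line.lower().startswith("codon"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected codon<TAB>freq")
            codon = parts[0].upper().replace("U", "T")
            usage[codon] = float(parts[1])
    return usage
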