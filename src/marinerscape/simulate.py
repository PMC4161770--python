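"""Forward simulator: genomes with planted mariner lineages and full truth.

The generative model mirrors the inferred element life cycle: one master
element per lineage amplifies under a time-varying per-copy transposition
rate (a burst profile); every living copy accumulates substitutions,
internal deletions, end truncations and small insertions as independent
point processes; transposition copies the parent's CURRENT sequence, so
deletions that occurred before a transposition are shared by descendants
(exercising the count-shared-deletions-once rule). A configured MITE
genesis event turns one copy into a short derivative (internal deletion or
5'->3' rearrangement) whose descendants form the MITE sublineage. Copies
are planted into a background genome at TA dinucleotides (duplicated on
insertion) with a configurable flanking A/T bias; segmental duplications
copy an insertion together with its flanks.

Simulation time is measured so that burst ages are directly comparable to
LTT output: with substitution_rate mu, an event at age a sits at mu*a
substitutions/site in the reconstructed trees (truth tables record both).
Reproducibility contract: identical config + seed => identical output bytes.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .model import GenomeSequence, Interval, revcomp
from .io import write_fasta
from .panel import default_panel, panel_entry

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODON_CHOICES: dict[str, list[str]] = {}


def _codon_choices() -> dict[str, list[str]]:
    if not _CODON_CHOICES:
        from .search import _codon_map
        inv: dict[str, list[str]] = {}
        for codon, aa in _codon_map().items():
            inv.setdefault(aa, []).append(codon)
        for v in inv.values():
            v.sort()
        _CODON_CHOICES.update(inv)
    return _CODON_CHOICES


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RateFunction:
    """Per-copy transposition rate as a function of AGE before present.

    kinds: constant (rate); burst (gaussian: center_age, width, height);
    double_burst (two gaussians); ongoing (base + gaussian at age 0).
    """

    kind: str = "constant"
    rate: float = 0.0
    center_age: float = 0.1
    width: float = 0.02
    height: float = 0.0
    second_center_age: float = 0.0
    second_height: float = 0.0
    base: float = 0.0

    def __call__(self, age: float) -> float:
        def gauss(center: float, h: float) -> float:
            return h * float(np.exp(-0.5 * ((age - center) / self.width) ** 2))
        if self.kind == "constant":
            return self.rate
        if self.kind == "burst":
            return gauss(self.center_age, self.height)
        if self.kind == "double_burst":
            return gauss(self.center_age, self.height) + \
                gauss(self.second_center_age, self.second_height)
        if self.kind == "ongoing":
            return self.base + gauss(0.0, self.height)
        raise ValueError(f"unknown rate kind {self.kind!r}")

    @staticmethod
    def from_dict(d: dict) -> "RateFunction":
        allowed = {f.name for f in dataclasses.fields(RateFunction)}
        bad = set(d) - allowed
        if bad:
            raise ValueError(f"unknown rate keys: {sorted(bad)}")
        return RateFunction(**d)


@dataclass(frozen=True)
class MiteEvent:
    """MITE genesis: at ``time`` one copy acquires the configured lesion."""

    time: float
    type: str  # "deletion" | "rearrangement"
    start: int = 0   # deletion interval (master coordinates)
    end: int = 0
    kept_5prime: int = 0      # rearrangement: copy = C[0:x] + revcomp(C[0:y])
    inverted_5prime: int = 0

    @staticmethod
    def from_dict(d: dict) -> "MiteEvent":
        allowed = {f.name for f in dataclasses.fields(MiteEvent)}
        bad = set(d) - allowed
        if bad:
            raise ValueError(f"unknown mite_event keys: {sorted(bad)}")
        return MiteEvent(**d)


@dataclass(frozen=True)
class LineageSpec:
    name: str
    rate: RateFunction
    master_sequence: str | None = None
    master_length: int = 1286
    tir_length: int = 30
    orf_codons: int = 345
    substitution_rate: float = 0.3
    internal_deletion_rate: float = 0.0
    deletion_mean_nt: float = 80.0
    truncation_rate: float = 0.0
    truncation_mean_nt: float = 150.0
    insertion_rate: float = 0.0
    insertion_mean_nt: float = 8.0
    mite_event: MiteEvent | None = None
    flank_at_bias: float = 0.5
    segmental_duplications: int = 0
    panel_reference: str | None = None
    panel_divergence: float = 0.15
    # conditioning: the analysis concerns lineages that actually amplified,
    # so the scenario may require a copy-count window (and a minimum number
    # of MITE copies); the simulator redraws the lineage until satisfied
    min_copies: int = 0
    max_lineage_copies: int = 0  # 0 = unbounded
    require_mite_copies: int = 0
    max_attempts: int = 64

    @staticmethod
    def from_dict(d: dict) -> "LineageSpec":
        d = dict(d)
        allowed = {f.name for f in dataclasses.fields(LineageSpec)}
        bad = set(d) - allowed
        if bad:
            raise ValueError(f"unknown lineage keys: {sorted(bad)}")
        if "rate" in d and isinstance(d["rate"], dict):
            d["rate"] = RateFunction.from_dict(d["rate"])
        if d.get("mite_event") is not None and isinstance(d["mite_event"], dict):
            d["mite_event"] = MiteEvent.from_dict(d["mite_event"])
        return LineageSpec(**d)


@dataclass(frozen=True)
class SimConfig:
    genome_length: int
    gc_content: float
    seed: int
    lineages: tuple[LineageSpec, ...]
    total_time: float = 0.30
    dt: float = 0.0025
    max_copies: int = 2000
    min_site_separation: int = 600
    scaffold_id: str = "contig1"

    @staticmethod
    def from_dict(d: dict) -> "SimConfig":
        d = dict(d)
        allowed = {f.name for f in dataclasses.fields(SimConfig)}
        bad = set(d) - allowed
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        d["lineages"] = tuple(LineageSpec.from_dict(x) for x in d.get("lineages", ()))
        return SimConfig(**d)


def load_scenario(path) -> SimConfig:
    with open(path) as fh:
        return SimConfig.from_dict(yaml.safe_load(fh))


def default_scenario() -> SimConfig:
    return load_scenario(Path(__file__).parent / "data" / "default_scenario.yaml")


# ---------------------------------------------------------------------------
# master elements
# ---------------------------------------------------------------------------

def back_translate(protein: str, rng: np.random.Generator) -> str:
    choices = _codon_choices()
    return "".join(rng.choice(choices[aa]) for aa in protein)


def mutate_protein(protein: str, divergence: float,
                   rng: np.random.Generator) -> str:
    from .panel import AA20, plant_triad
    p = list(protein)
    n_mut = rng.binomial(len(p), divergence)
    for pos in rng.choice(len(p), size=n_mut, replace=False):
        alt = [a for a in AA20 if a != p[pos]]
        p[pos] = alt[int(rng.integers(len(alt)))]
    return plant_triad("".join(p), "D")  # keep the catalytic triad intact


def generate_master(rng: np.random.Generator, length: int = 1286,
                    tir_length: int = 30, orf_codons: int = 345,
                    protein: str | None = None) -> str:
    """A synthetic full-length mariner-like master element.

    Geometry mirrors the family's canonical structure: ~1.3 kb, terminal
    inverted repeats, one stop-free ORF of ``orf_codons`` codons flanked by
    in-frame stops; the longest stop-free run over the three forward frames
    equals ``orf_codons`` exactly.
    """
    from .annotation import scan_orf
    orf_nt = 3 * orf_codons
    orf_start = tir_length + 60
    if orf_start + orf_nt + 3 + tir_length >= length:
        raise ValueError("master too short for the requested ORF")
    if protein is None:
        from .panel import AA20
        protein = "".join(rng.choice(list(AA20), size=orf_codons))
    if len(protein) != orf_codons:
        raise ValueError("protein length must equal orf_codons")
    orf_seq = back_translate(protein, rng)
    for _attempt in range(100):
        seq = list("".join(rng.choice(list("ACGT"), size=length)))
        tir = "".join(rng.choice(list("ACGT"), size=tir_length))
        seq[:tir_length] = tir
        seq[length - tir_length:] = revcomp(tir)
        seq[orf_start - 3:orf_start] = "TAA"
        seq[orf_start:orf_start + orf_nt] = orf_seq
        seq[orf_start + orf_nt:orf_start + orf_nt + 3] = "TAA"
        master = "".join(seq)
        if scan_orf(master) == orf_codons:
            return master
    raise RuntimeError("could not satisfy the ORF-length constraint")


# ---------------------------------------------------------------------------
# lineage evolution
# ---------------------------------------------------------------------------

@dataclass
class SimCopy:
    id: str
    lineage: str
    parent: str | None
    birth_time: float
    res: np.ndarray            # uint8 ASCII residues
    coords: np.ndarray         # int32 master coordinate per base, -1 = novel
    is_mite: bool = False
    mite_founder: bool = False
    events: list = field(default_factory=list)
    location: Interval | None = None
    strand: str = "+"
    is_segmental_duplicate: bool = False

    @property
    def sequence(self) -> str:
        return self.res.tobytes().decode("ascii")


@dataclass
class LineageResult:
    spec: LineageSpec
    master: str
    copies: list[SimCopy]
    events: list
    truncated: bool
    burst_age_divergence: float  # mu * dominant burst age (0 for constant)


def _mutate_step(c: SimCopy, spec: LineageSpec, dt: float, t: float,
                 rng: np.random.Generator, events: list) -> None:
    L = len(c.res)
    if L < 60:
        return
    n_sub = rng.poisson(spec.substitution_rate * L * dt)
    if n_sub:
        pos = rng.integers(0, L, size=n_sub)
        for p in pos:
            old = c.res[p]
            alts = _BASES[_BASES != old]
            c.res[p] = alts[int(rng.integers(3))]
            events.append((c.id, t, "substitution", int(c.coords[p]), int(c.coords[p]) + 1, 1))
    if spec.internal_deletion_rate and rng.random() < spec.internal_deletion_rate * dt:
        size = int(rng.geometric(1.0 / spec.deletion_mean_nt))
        L = len(c.res)
        if 0 < size and L - size >= 120:
            start = int(rng.integers(1, L - size))
            m0 = int(c.coords[start]); m1 = int(c.coords[start + size - 1]) + 1
            c.res = np.delete(c.res, slice(start, start + size))
            c.coords = np.delete(c.coords, slice(start, start + size))
            events.append((c.id, t, "internal_deletion", m0, m1, size))
    if spec.truncation_rate and rng.random() < spec.truncation_rate * dt:
        size = int(rng.geometric(1.0 / spec.truncation_mean_nt))
        L = len(c.res)
        if 0 < size and L - size >= 120:
            if rng.random() < 0.5:
                m0, m1 = int(c.coords[0]), int(c.coords[size - 1]) + 1
                c.res, c.coords = c.res[size:], c.coords[size:]
                events.append((c.id, t, "truncation_left", m0, m1, size))
            else:
                m0, m1 = int(c.coords[L - size]), int(c.coords[L - 1]) + 1
                c.res, c.coords = c.res[:L - size], c.coords[:L - size]
                events.append((c.id, t, "truncation_right", m0, m1, size))
    if spec.insertion_rate and rng.random() < spec.insertion_rate * dt:
        size = int(rng.geometric(1.0 / spec.insertion_mean_nt))
        pos = int(rng.integers(1, len(c.res)))
        ins = rng.choice(_BASES, size=size)
        c.res = np.concatenate([c.res[:pos], ins, c.res[pos:]])
        c.coords = np.concatenate(
            [c.coords[:pos], np.full(size, -1, np.int32), c.coords[pos:]])
        m = int(c.coords[pos - 1])
        events.append((c.id, t, "insertion", m, m + 1, size))


def _apply_mite(c: SimCopy, ev: MiteEvent, t: float, events: list) -> bool:
    if ev.type == "deletion":
        mask = (c.coords >= ev.start) & (c.coords < ev.end)
        if not mask.any():
            return False
        c.res = c.res[~mask]
        c.coords = c.coords[~mask]
        events.append((c.id, t, "mite_deletion", ev.start, ev.end, int(mask.sum())))
    elif ev.type == "rearrangement":
        keep = np.nonzero(c.coords >= 0)[0]
        lx = int(np.searchsorted(c.coords[keep], ev.kept_5prime))
        ly = int(np.searchsorted(c.coords[keep], ev.inverted_5prime))
        if lx == 0 or ly == 0:
            return False
        lx, ly = int(keep[min(lx, len(keep) - 1)]), int(keep[min(ly, len(keep) - 1)])
        inv = np.frombuffer(revcomp(c.res[:ly].tobytes().decode("ascii")).encode(),
                            dtype=np.uint8).copy()
        c.res = np.concatenate([c.res[:lx], inv])
        c.coords = np.concatenate([c.coords[:lx], np.full(len(inv), -1, np.int32)])
        events.append((c.id, t, "mite_rearrangement",
                       ev.kept_5prime, ev.inverted_5prime, len(inv)))
    else:
        raise ValueError(f"unknown mite event type {ev.type!r}")
    c.is_mite = True
    c.mite_founder = True
    return True


def evolve_lineage(spec: LineageSpec, total_time: float,
                   rng: np.random.Generator, dt: float = 0.0025,
                   max_copies: int = 2000) -> LineageResult:
    """Discrete-time branching simulation of one lineage.

    Each living copy transposes with probability rate(age)*dt per step
    (the child snapshots the parent's current, mutated sequence) and
    accumulates substitutions/indels as independent point processes.
    Events are appended to the truth log as they happen.
    """
    if spec.master_sequence is not None:
        master = spec.master_sequence.upper()
    else:
        protein = None
        if spec.panel_reference is not None:
            base = panel_entry(spec.panel_reference).sequence
            protein = mutate_protein(base, spec.panel_divergence, rng)
        master = generate_master(rng, spec.master_length, spec.tir_length,
                                 spec.orf_codons, protein)
    events: list = []
    founder = SimCopy(id=f"{spec.name}_c0000", lineage=spec.name, parent=None,
                      birth_time=0.0,
                      res=np.frombuffer(master.encode(), dtype=np.uint8).copy(),
                      coords=np.arange(len(master), dtype=np.int32))
    copies = [founder]
    truncated = False
    mite_done = spec.mite_event is None
    steps = int(round(total_time / dt))
    serial = 1
    for s in range(steps):
        t = s * dt
        age = total_time - t
        p_t = spec.rate(age) * dt
        if not mite_done and t >= spec.mite_event.time:
            eligible = [c for c in copies[1:] if not c.is_mite]
            if eligible:
                target = eligible[int(rng.integers(len(eligible)))]
                mite_done = _apply_mite(target, spec.mite_event, t, events)
        n_now = len(copies)
        for idx in range(n_now):
            c = copies[idx]
            if not truncated and p_t > 0 and rng.random() < p_t:
                child = SimCopy(id=f"{spec.name}_c{serial:04d}", lineage=spec.name,
                                parent=c.id, birth_time=t,
                                res=c.res.copy(), coords=c.coords.copy(),
                                is_mite=c.is_mite)
                serial += 1
                copies.append(child)
                events.append((c.id, t, "transposition", -1, -1, 0))
                if len(copies) >= max_copies:
                    truncated = True
            _mutate_step(c, spec, dt, t, rng, events)
    rf = spec.rate
    if rf.kind in {"burst", "double_burst"}:
        burst_age = rf.center_age
    elif rf.kind == "ongoing":
        burst_age = 0.0
    else:
        burst_age = float("nan")
    return LineageResult(spec=spec, master=master, copies=copies, events=events,
                         truncated=truncated,
                         burst_age_divergence=spec.substitution_rate * burst_age)


# ---------------------------------------------------------------------------
# TA insertion sites
# ---------------------------------------------------------------------------

def ta_sites_and_weights(residues: str, flank_at_bias: float,
                         margin: int = 700) -> tuple[np.ndarray, np.ndarray]:
    """TA positions and bias weights: product over offsets +-1..3 of
    (bias if A/T else 1-bias); uniform at bias 0.5."""
    arr = np.frombuffer(residues.encode("ascii"), dtype=np.uint8)
    is_t = arr == ord("T")
    is_a = arr == ord("A")
    at = is_t | is_a
    sites = np.nonzero(is_t[:-1] & is_a[1:])[0]
    lo = max(margin, 3)           # the +-3 context must exist
    hi = len(arr) - max(margin, 5)
    sites = sites[(sites >= lo) & (sites <= hi)]
    if sites.size == 0:
        raise ValueError("genome contains no eligible TA site")
    w = np.ones(sites.size, dtype=float)
    b = flank_at_bias
    for off in (-3, -2, -1):
        w *= np.where(at[sites + off], b, 1.0 - b)
    for off in (1, 2, 3):
        w *= np.where(at[sites + 1 + off], b, 1.0 - b)
    return sites, w / w.sum()


def sample_insertion_site(residues: str, flank_at_bias: float,
                          rng: np.random.Generator, margin: int = 0) -> int:
    """Draw one TA insertion site (position of the T) with flanking A/T bias."""
    sites, w = ta_sites_and_weights(residues, flank_at_bias, margin=max(0, margin))
    return int(sites[rng.choice(sites.size, p=w)])


def insert_at_ta(genome: str, element: str, site: int) -> str:
    """Insert an element at a TA dinucleotide, duplicating the TA."""
    if genome[site:site + 2] != "TA":
        raise ValueError(f"no TA at site {site}")
    return genome[:site + 2] + element + "TA" + genome[site + 2:]


# ---------------------------------------------------------------------------
# genome assembly and emission
# ---------------------------------------------------------------------------

@dataclass
class SimResult:
    config: SimConfig
    genome: GenomeSequence
    lineages: list[LineageResult]
    copies: list[SimCopy]         # all placed copies incl. segmental duplicates
    background_length: int

    def truth_rows(self) -> list[dict]:
        rows = []
        for c in self.copies:
            rows.append(dict(
                id=c.id, lineage=c.lineage, parent=c.parent or "",
                birth_time=round(c.birth_time, 6),
                scaffold=c.location.scaffold_id, start=c.location.start,
                end=c.location.end, strand=c.strand, length=len(c.res),
                is_mite=int(c.is_mite),
                is_segmental_duplicate=int(c.is_segmental_duplicate)))
        return rows


def _random_background(rng: np.random.Generator, length: int,
                       gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=length, p=p).tobytes().decode("ascii")


def run_simulation(config: SimConfig) -> SimResult:
    """Simulate lineages, place every copy at a biased TA site, emit truth.

    Placement keeps a minimum separation between insertions so flanks stay
    informative (no nested insertions arise); segmental duplications copy
    a planted insertion together with ~300 nt of each flank to a new locus.
    """
    rng = np.random.default_rng(config.seed)
    background = _random_background(rng, config.genome_length, config.gc_content)
    lineage_results = []
    for spec in config.lineages:
        attempt_seeds = np.random.default_rng(rng.integers(2 ** 31)).integers(
            2 ** 31, size=max(1, spec.max_attempts))
        best = None
        best_score = -1.0
        for aseed in attempt_seeds:
            res = evolve_lineage(spec, config.total_time,
                                 np.random.default_rng(int(aseed)),
                                 config.dt, config.max_copies)
            n = len(res.copies)
            n_mite = sum(c.is_mite for c in res.copies)
            ok_n = n >= spec.min_copies and \
                (spec.max_lineage_copies == 0 or n <= spec.max_lineage_copies)
            ok_m = n_mite >= spec.require_mite_copies
            if ok_n and ok_m:
                best = res
                break
            score = min(n, spec.min_copies or n) + min(n_mite, spec.require_mite_copies)
            if spec.max_lineage_copies and n > spec.max_lineage_copies:
                score -= (n - spec.max_lineage_copies) / spec.max_lineage_copies
            if score > best_score:
                best, best_score = res, score
        lineage_results.append(best)

    # choose insertion sites in the ORIGINAL background, then build once
    placements: list[tuple[int, SimCopy, str]] = []
    chosen: list[int] = []
    min_sep = config.min_site_separation
    for res in lineage_results:
        sites, weights = ta_sites_and_weights(
            background, res.spec.flank_at_bias, margin=700)
        for c in res.copies:
            site = None
            for _try in range(2000):
                cand = int(sites[rng.choice(sites.size, p=weights)])
                if all(abs(cand - o) >= min_sep for o in chosen):
                    site = cand
                    break
            if site is None:
                raise RuntimeError("could not place all copies; genome too small")
            chosen.append(site)
            strand = "+" if rng.random() < 0.5 else "-"
            placements.append((site, c, strand))
    placements.sort(key=lambda x: x[0])

    pieces = []
    cursor = 0
    offset = 0
    for site, c, strand in placements:
        pieces.append(background[cursor:site + 2])
        start = site + 2 + offset
        elem = c.sequence if strand == "+" else revcomp(c.sequence)
        pieces.append(elem + "TA")
        c.location = Interval(config.scaffold_id, start, start + len(elem), strand)
        c.strand = strand
        offset += len(elem) + 2
        cursor = site + 2
    pieces.append(background[cursor:])
    genome_str = "".join(pieces)

    # segmental duplications: copy insertion + ~300 nt flanks to a new locus
    all_copies: list[SimCopy] = [c for _s, c, _st in placements]
    flank = 300
    for res in lineage_results:
        n_dups = res.spec.segmental_duplications
        if n_dups <= 0:
            continue
        members = [c for c in res.copies if c.location is not None]
        mites = [c for c in members if c.is_mite]
        sources = []
        if mites:
            sources.append(mites[int(rng.integers(len(mites)))])
        while len(sources) < min(n_dups, len(members)):
            cand = members[int(rng.integers(len(members)))]
            if cand not in sources:
                sources.append(cand)
        for k, src in enumerate(sources, start=1):
            blk0 = max(0, src.location.start - 2 - flank)
            blk1 = min(len(genome_str), src.location.end + 2 + flank)
            block = genome_str[blk0:blk1]
            rel = src.location.start - blk0  # element offset inside the block
            pos = None
            for _try in range(2000):
                cand = int(rng.integers(700, len(genome_str) - 700))
                if all(min(abs(cand - c.location.start),
                           abs(cand - c.location.end)) >= min_sep
                       for c in all_copies):
                    pos = cand
                    break
            if pos is None:
                continue
            genome_str = genome_str[:pos] + block + genome_str[pos:]
            for c in all_copies:
                if c.location.start >= pos:
                    c.location = Interval(c.location.scaffold_id,
                                          c.location.start + len(block),
                                          c.location.end + len(block),
                                          c.location.strand)
            dstart = pos + rel
            dup = SimCopy(id=f"{src.id}_dup{k}", lineage=src.lineage,
                          parent=src.id, birth_time=src.birth_time,
                          res=src.res.copy(), coords=src.coords.copy(),
                          is_mite=src.is_mite, is_segmental_duplicate=True,
                          strand=src.strand,
                          location=Interval(config.scaffold_id, dstart,
                                            dstart + len(src.res), src.strand))
            all_copies.append(dup)
            res.copies.append(dup)

    genome = GenomeSequence(config.scaffold_id, genome_str)
    all_copies.sort(key=lambda c: c.location.start)
    return SimResult(config=config, genome=genome, lineages=lineage_results,
                     copies=all_copies,
                     background_length=config.genome_length)


def emit(result: SimResult, out_dir) -> dict[str, Path]:
    """Write genome FASTA, master FASTA, truth TSV/GFF3 (byte-deterministic)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": out / "genome.fasta",
        "masters": out / "masters.fasta",
        "truth_copies": out / "truth_copies.tsv",
        "truth_events": out / "truth_events.tsv",
        "truth_gff": out / "truth.gff3",
    }
    write_fasta([result.genome], paths["genome"])
    write_fasta([(r.spec.name, r.master) for r in result.lineages],
                paths["masters"])
    cols = ["id", "lineage", "parent", "birth_time", "scaffold", "start",
            "end", "strand", "length", "is_mite", "is_segmental_duplicate"]
    with open(paths["truth_copies"], "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for row in result.truth_rows():
            fh.write("\t".join(str(row[c]) for c in cols) + "\n")
    with open(paths["truth_events"], "w") as fh:
        fh.write("copy_id\ttime\ttype\tmaster_start\tmaster_end\tsize\n")
        for r in result.lineages:
            for ev in r.events:
                fh.write("\t".join([ev[0], f"{ev[1]:.6f}", ev[2],
                                    str(ev[3]), str(ev[4]), str(ev[5])]) + "\n")
    with open(paths["truth_gff"], "w") as fh:
        fh.write("##gff-version 3\n")
        for c in result.copies:
            attrs = (f"ID={c.id};lineage={c.lineage};mite={str(c.is_mite).lower()};"
                     f"segdup={str(c.is_segmental_duplicate).lower()}")
            fh.write("\t".join([
                c.location.scaffold_id, "sim", "mobile_genetic_element",
                str(c.location.start + 1), str(c.location.end), ".",
                c.location.strand, ".", attrs]) + "\n")
    return paths


# ---------------------------------------------------------------------------
# focused helpers for statistics and dynamics studies
# ---------------------------------------------------------------------------

def plant_insertions(genome_length: int, gc: float, element: str, n: int,
                     flank_at_bias: float, rng: np.random.Generator,
                     min_sep: int = 10
                     ) -> tuple[GenomeSequence, list, GenomeSequence]:
    """Plant n copies of one element at biased TA sites.

    Returns (genome with insertions, clean TECopy records with 250-nt
    flanks, the pre-insertion background genome). The background genome is
    the right reference for context statistics when the planted fraction
    is large: thousands of identical element copies would otherwise
    contribute their own fixed TA contexts to the genome-wide background.
    """
    from .model import TECopy
    background = _random_background(rng, genome_length, gc)
    sites, weights = ta_sites_and_weights(background, flank_at_bias, margin=300)
    cum = np.cumsum(weights)
    chosen: list[int] = []
    taken = np.zeros(len(background), dtype=bool)
    for _ in range(n):
        for _try in range(5000):
            idx = int(np.searchsorted(cum, rng.random() * cum[-1]))
            cand = int(sites[min(idx, sites.size - 1)])
            if not taken[max(0, cand - min_sep):cand + min_sep].any():
                chosen.append(cand)
                taken[cand] = True
                break
        else:
            raise RuntimeError("could not place all insertions")
    chosen.sort()
    copies = []
    pieces = []
    cursor = 0
    offset = 0
    for site in chosen:
        pieces.append(background[cursor:site + 2])
        start = site + 2 + offset
        pieces.append(element + "TA")
        copies.append((start, start + len(element)))
        offset += len(element) + 2
        cursor = site + 2
    pieces.append(background[cursor:])
    genome_str = "".join(pieces)
    out = []
    for i, (s, e) in enumerate(copies):
        out.append(TECopy(id=f"ins{i:04d}",
                          location=Interval("bias_genome", s, e, "+"),
                          residues=genome_str[s:e],
                          left_flank=genome_str[max(0, s - 250):s],
                          right_flank=genome_str[e:e + 250]))
    return (GenomeSequence("bias_genome", genome_str), out,
            GenomeSequence("bias_background", background))


def star_lineage(n_copies: int, divergence: float, rng: np.random.Generator,
                 length: int = 1286, deletion_rate_nt_per_sub: float = 0.0,
                 deletion_mean_nt: float = 60.0,
                 master: str | None = None) -> tuple[str, list[str]]:
    """Independent copies diverged from a common master (a star genealogy).

    Each copy receives Binomial(L, divergence) substitutions; optionally
    internal deletions are added so the expected deleted-nt to substitution
    ratio equals ``deletion_rate_nt_per_sub``. Returns (master, copies).
    """
    if master is None:
        master = generate_master(rng, length=length)
    L = len(master)
    copies = []
    for _ in range(n_copies):
        seq = master
        if deletion_rate_nt_per_sub > 0:
            # deletions first, substitutions on the surviving sites: the
            # measured ratio divides deleted nt by surviving substitutions,
            # so the target must be calibrated against the post-deletion
            # length:  E[D] = r d L / (1 + r d)
            rd = deletion_rate_nt_per_sub * divergence
            target_nt = rd * L / (1.0 + rd)
            n_del = rng.poisson(target_nt / deletion_mean_nt)
            for _d in range(n_del):
                size = int(rng.geometric(1.0 / deletion_mean_nt))
                if len(seq) - size < 200:
                    continue
                start = int(rng.integers(30, len(seq) - size - 30))
                seq = seq[:start] + seq[start + size:]
        arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
        n_sub = rng.binomial(len(arr), divergence)
        pos = rng.choice(len(arr), size=n_sub, replace=False)
        for p in pos:
            alts = _BASES[_BASES != arr[p]]
            arr[p] = alts[int(rng.integers(3))]
        copies.append(arr.tobytes().decode())
    return master, copies


DYNAMICS_SCENARIOS: dict[str, tuple[RateFunction, float]] = {
    # canonical study conditions for amplification-dynamics recovery;
    # time unit = substitutions/site (mu = 1), so ages are divergence units
    "constant": (RateFunction(kind="constant", rate=18.0), 0.23),
    "single_burst": (RateFunction(kind="burst", center_age=0.10, width=0.02,
                                  height=92.0), 0.15),
    "double_burst": (RateFunction(kind="double_burst", center_age=0.20,
                                  width=0.02, height=46.0,
                                  second_center_age=0.05, second_height=46.0),
                     0.25),
    "ongoing": (RateFunction(kind="ongoing", base=4.0, width=0.03,
                             height=80.0), 0.25),
}

DYNAMICS_LABELS = {
    "constant": "constant",
    "single_burst": "single_burst_then_decay",
    "double_burst": "multiple_bursts",
    "ongoing": "ongoing_burst",
}


def simulate_dynamics_case(kind: str, seed: int, min_leaves: int = 16,
                           max_copies: int = 220, max_attempts: int = 40
                           ) -> tuple["LineageResult", list[str], str]:
    """One dynamics scenario conditioned on successful amplification.

    Lineages that go extinct or stay tiny carry no dynamics signal, so the
    draw is repeated (with derived seeds) until at least ``min_leaves``
    copies exist. Returns (result, aligned copy rows, outgroup row).
    """
    rate, total_time = DYNAMICS_SCENARIOS[kind]
    seeds = np.random.default_rng(seed).integers(2 ** 31, size=max_attempts)
    best = None
    for aseed in seeds:
        rng = np.random.default_rng(int(aseed))
        res, rows, outgroup = birth_process_rows(rate, total_time, rng,
                                                 max_copies=max_copies)
        ok = len(rows) >= min_leaves
        if ok and kind == "ongoing":
            # an ongoing burst is only distinguishable from rate constancy
            # when the founder predates the burst: require a transposition
            # in the pre-burst era
            first = min((ev[1] for ev in res.events
                         if ev[2] == "transposition"), default=None)
            ok = first is not None and first <= total_time - 0.15
        if ok:
            return res, rows, outgroup
        if best is None or len(rows) > len(best[1]):
            best = (res, rows, outgroup)
    return best


def birth_process_rows(rate: RateFunction, total_time: float,
                       rng: np.random.Generator, substitution_rate: float = 1.0,
                       length: int = 1286, max_copies: int = 300,
                       dt: float = 0.002) -> tuple[LineageResult, list[str], str]:
    """Sequence-level birth simulation for dynamics studies (no indels).

    Returns the lineage result, the copy sequences (equal length, already
    'aligned' since no indels occur) and an outgroup sequence: the master
    mutated to ~25% divergence, standing in for a sister lineage consensus.
    """
    spec = LineageSpec(name="dyn", rate=rate, substitution_rate=substitution_rate,
                       master_length=length)
    res = evolve_lineage(spec, total_time, rng, dt=dt, max_copies=max_copies)
    rows = [c.sequence for c in res.copies]
    arr = np.frombuffer(res.master.encode(), dtype=np.uint8).copy()
    n_mut = rng.binomial(length, 0.25)
    for p in rng.choice(length, size=n_mut, replace=False):
        alts = _BASES[_BASES != arr[p]]
        arr[p] = alts[int(rng.integers(3))]
    return res, rows, arr.tobytes().decode()
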