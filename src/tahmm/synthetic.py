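"""Labelled synthetic sequence generators for the four sequence classes.

Real curated datasets of tail-anchored (TA), signal-anchored single-pass
(SP), multi-pass (MP) and non-membrane (NO) proteins cannot be shipped, so
this module draws labelled sequences from ground-truth region-structured
HMMs built on the topologies of :mod:`tahmm.topologies`, with emission
profiles chosen to mimic the compositional signal of each class:

* transmembrane segments are strongly hydrophobic,
* cap segments are enriched in basic residues,
* tails, inter-TMD loops and translocated (luminal/secreted) protein bodies
  are hydrophilic-biased,
* the cytosolic globular body of a TA protein has an average (database
  background) composition.

The last point reflects real biology — a TA protein's body stays in the
cytosol while SP/MP/NO bodies are translocated and measurably more polar —
and it is what gives the four classes distinct likelihood signatures.

A ``difficulty`` knob interpolates every emission profile linearly toward
the uniform distribution: 1.0 keeps the full class separation, 0.0 erases
it entirely.

The true region annotation of every generated record is the generator's
sampled state path mapped to regions, expressed in N->C coordinates
(0-based, half-open).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alphabet import ALPHABET, N_SYMBOLS, AminoAcidSequence
from .hmm import READS_C_TO_N, HmmParameters, sample_sequence
from .topologies import build_mp_model, build_sp_model, build_ta_model

CLASSES = ("TA", "SP", "MP", "NO")

# Swiss-Prot-like average amino-acid frequencies (percent), used as the
# background composition of cytosolic globular domains.
_BACKGROUND_PCT = {
    "A": 8.25, "C": 1.38, "D": 5.46, "E": 6.72, "F": 3.86,
    "G": 7.07, "H": 2.27, "I": 5.91, "K": 5.80, "L": 9.65,
    "M": 2.41, "N": 4.06, "P": 4.74, "Q": 3.93, "R": 5.53,
    "S": 6.64, "T": 5.35, "V": 6.86, "W": 1.10, "Y": 2.92,
}


def _profile_from_classes(favoured: str, mass: float) -> np.ndarray:
    from .alphabet import RESIDUE_CLASSES

    members = RESIDUE_CLASSES[favoured]
    row = np.empty(N_SYMBOLS)
    for k, a in enumerate(ALPHABET):
        row[k] = (
            mass / len(members)
            if a in members
            else (1.0 - mass) / (N_SYMBOLS - len(members))
        )
    return row


def _background() -> np.ndarray:
    row = np.array([_BACKGROUND_PCT[a] for a in ALPHABET])
    return row / row.sum()


#: Ground-truth emission profiles at difficulty 1.0.
GENERATOR_PROFILES: dict[str, np.ndarray] = {
    "hydrophilic_rich": _profile_from_classes("hydrophilic", 0.85),
    "hydrophobic_rich": _profile_from_classes("hydrophobic", 0.85),
    "basic_rich": _profile_from_classes("basic", 0.60),
    "background": _background(),
}

#: Per-class mapping of region label -> profile name.
_REGION_PROFILE: dict[str, dict[str, str]] = {
    "TA": {
        "tail": "hydrophilic_rich",
        "TMD": "hydrophobic_rich",
        "cap": "basic_rich",
        "globular": "background",
    },
    "SP": {
        "signal_basic": "basic_rich",
        "signal_hydrophobic": "hydrophobic_rich",
        "signal_polar": "hydrophilic_rich",
        "globular1": "hydrophilic_rich",
        "cap": "basic_rich",
        "TMD": "hydrophobic_rich",
        "globular2": "hydrophilic_rich",
    },
    "MP": {
        "signal_basic": "basic_rich",
        "signal_hydrophobic": "hydrophobic_rich",
        "signal_polar": "hydrophilic_rich",
        "globular": "hydrophilic_rich",
        "cap": "basic_rich",
        "TMD": "hydrophobic_rich",
        "loop": "hydrophilic_rich",
    },
}

#: Dwell probability of a generator tail state; mean tail length with two
#: tail states is about 7 residues, matching the short tails of TA proteins.
_TAIL_SELF = 0.7

#: Dwell probability of generator globular states that have an exit
#: (SP globular(1), MP globular): real extramembrane domains are tens to
#: hundreds of residues long, not the 2-residue runs a uniform transition
#: row would produce.
_GLOB_SELF = 0.95

#: Generator loop advance probability; mean loop length ~5-6 residues
#: (real inter-TMD loops are a handful to ~20 residues).
_LOOP_ADVANCE = 0.8


@dataclass(frozen=True)
class SyntheticRecord:
    """A generated sequence with its ground-truth class and annotation."""

    sequence: AminoAcidSequence
    true_class: str
    #: (region label, start, end) in 0-based half-open N->C coordinates;
    #: the segments tile the sequence.
    segments: tuple[tuple[str, int, int], ...]

    def tmd_segments(self) -> list[tuple[str, int, int]]:
        return [s for s in self.segments if s[0] == "TMD"]


def make_generator(true_class: str, difficulty: float = 1.0) -> HmmParameters:
    """Ground-truth HMM for one sequence class.

    ``difficulty`` in [0, 1] scales how far the class emission profiles sit
    from the uniform distribution (1.0 = fully separated classes).
    """
    if true_class not in CLASSES:
        raise ValueError(f"unknown class {true_class!r}")
    if not 0.0 <= difficulty <= 1.0:
        raise ValueError("difficulty must be in [0, 1]")
    if true_class == "NO":
        params = _single_state_model()
    elif true_class == "TA":
        params = build_ta_model(2)
    elif true_class == "SP":
        params = build_sp_model()
    else:
        params = build_mp_model()
    profile_map = _REGION_PROFILE.get(true_class, {"globular": "hydrophilic_rich"})
    uniform = np.full(N_SYMBOLS, 1.0 / N_SYMBOLS)
    em = np.empty_like(params.log_emission)
    for i, region in enumerate(params.regions):
        row = GENERATOR_PROFILES[profile_map[region]]
        em[i] = difficulty * row + (1.0 - difficulty) * uniform
    params.log_emission = np.log(em)
    _set_dwell_dynamics(params, true_class)
    params.validate()
    return params


def _single_state_model() -> HmmParameters:
    return HmmParameters(
        state_ids=["glob"],
        regions=["globular"],
        log_initial=np.array([0.0]),
        log_transition=np.array([[0.0]]),
        log_emission=np.log(
            np.full((1, N_SYMBOLS), 1.0 / N_SYMBOLS)
        ),
        orientation="reads-N-to-C",
    )


def _set_self_dwell(params: HmmParameters, state: int, p_self: float) -> None:
    succ = np.flatnonzero(params.transition_mask[state])
    others = [j for j in succ if j != state]
    row = np.full(params.n_states, -np.inf)
    row[state] = np.log(p_self)
    for j in others:
        row[j] = np.log((1.0 - p_self) / len(others))
    params.log_transition[state] = row


def _set_dwell_dynamics(params: HmmParameters, true_class: str) -> None:
    """Give generator regions realistic run-length statistics.

    The model topologies start from uniform transition rows (those are
    re-estimated during training anyway), but a *generator* standing in
    for real proteins must produce realistic region lengths: short
    hydrophilic tails, extramembrane domains of tens to hundreds of
    residues, and inter-TMD loops of a handful of residues.
    """
    for i, region in enumerate(params.regions):
        if region == "tail":
            _set_self_dwell(params, i, _TAIL_SELF)
        elif region in ("globular", "globular1") and params.transition_mask[
            i
        ].sum() > 1:
            _set_self_dwell(params, i, _GLOB_SELF)
        elif region == "loop":
            succ = np.flatnonzero(params.transition_mask[i])
            nxt = [j for j in succ if params.regions[j] == "loop"]
            others = [j for j in succ if params.regions[j] != "loop"]
            row = np.full(params.n_states, -np.inf)
            if nxt:
                row[nxt[0]] = np.log(_LOOP_ADVANCE)
                rest = 1.0 - _LOOP_ADVANCE
            else:
                rest = 1.0
            for j in others:
                row[j] = np.log(rest / len(others))
            params.log_transition[i] = row


def _path_to_segments(
    regions: list[str], path: np.ndarray
) -> list[tuple[str, int, int]]:
    segs: list[tuple[str, int, int]] = []
    start = 0
    for t in range(1, len(path) + 1):
        if t == len(path) or regions[path[t]] != regions[path[start]]:
            segs.append((regions[path[start]], start, t))
            start = t
    return segs


def _reverse_segments(
    segs: list[tuple[str, int, int]], length: int
) -> list[tuple[str, int, int]]:
    return [(r, length - e, length - s) for (r, s, e) in reversed(segs)]


def _draw_length(rng: np.random.Generator, lo: int, hi: int, median: int) -> int:
    """Truncated log-normal length draw (sigma 0.45, resampled into range)."""
    for _ in range(1000):
        L = int(round(float(np.exp(rng.normal(np.log(median), 0.45)))))
        if lo <= L <= hi:
            return L
    return int(np.clip(median, lo, hi))


def _ta_truth_ok(segs: list[tuple[str, int, int]], length: int) -> bool:
    """Complete 15-25 residue TMD ending within 30 residues of the
    C-terminus, preceded (toward C) by a tail of at most 30 residues."""
    tmds = [s for s in segs if s[0] == "TMD"]
    if not tmds:
        return False
    last = tmds[-1]  # C-terminal-most TMD in N->C coordinates
    if not 15 <= last[2] - last[1] <= 25:
        return False
    if length - last[2] > 30:
        return False
    after = [s for s in segs if s[1] >= last[2]]
    return all(s[0] == "tail" for s in after)


def generate_dataset(
    true_class: str,
    n: int,
    seed,
    difficulty: float = 1.0,
    length_min: int = 50,
    length_max: int = 1000,
    length_median: int = 250,
) -> list[SyntheticRecord]:
    """Draw ``n`` labelled records of one class.

    Lengths follow a truncated log-normal (median 250, range 50-1000 by
    default), mirroring the length range where tail-anchored proteins are
    abundant.  TA records are rejection-sampled until the ground truth
    contains a complete 15-25 residue TMD within 30 residues of the
    C-terminus followed only by tail states, so every TA record is a
    *bona fide* tail-anchored architecture.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    gen = make_generator(true_class, difficulty)
    records: list[SyntheticRecord] = []
    for k in range(n):
        L = _draw_length(rng, length_min, length_max, length_median)
        for _attempt in range(1000):
            seq, path = sample_sequence(gen, L, rng)
            segs = _path_to_segments(gen.regions, path)
            if gen.orientation == READS_C_TO_N:
                seq = seq.reversed()
                segs = _reverse_segments(segs, L)
            if true_class != "TA" or _ta_truth_ok(segs, L):
                break
        else:  # pragma: no cover - astronomically unlikely
            raise RuntimeError("could not sample an admissible TA record")
        records.append(
            SyntheticRecord(
                sequence=AminoAcidSequence(
                    f"{true_class}_{k:04d}", seq.residues
                ),
                true_class=true_class,
                segments=tuple(segs),
            )
        )
    return records


def write_truth_tsv(records: list[SyntheticRecord], path) -> None:
    """Side-car truth annotation: id, class, region, start, end (0-based,
    half-open)."""
    with open(path, "w") as fh:
        fh.write("id\tclass\tregion\tstart\tend\n")
        for rec in records:
            for region, s, e in rec.segments:
                fh.write(
                    f"{rec.sequence.id}\t{rec.true_class}\t{region}\t{s}\t{e}\n"
                )
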