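"""Builders for the three region-structured HMM topologies.

Three models share a small grammar of biological regions:

* **TA model** (read C-terminus first): ``tail`` (2 or 4 states) ->
  ``TMD`` (25 states, first 14 forced) -> ``cap`` (5 states) ->
  ``globular`` (single self-loop).  The forced chain guarantees that every
  decoded transmembrane segment spans 15-25 residues, and the cap at most 5.
* **SP model** (read N-terminus first): a 40-state signal-peptide block
  (10 basic-biased, 15 hydrophobic-biased, 15 polar-biased states, exits
  allowed from state 15 onward, so decoded signals span 15-40 residues),
  then ``globular1`` -> ``cap`` -> ``TMD`` -> ``globular2``.
* **MP model**: as the SP model, but the TMD exits into a 20-state ``loop``
  region (decoded loops span 1-20 residues) whose states return to the cap
  or the globular state, so the model can thread multiple membrane passes.

Initial transition probabilities are uniform over each state's allowed
successors; initial state probability is split 0.5/0.5 between the two
entry regions of each model.  Initial emissions follow a 70/30 rule: 70 %
of the mass uniformly on the region's favoured residue class, 30 % on the
rest of the alphabet.  Training re-estimates all probabilities but can
never create a transition the topology forbids.
"""

from __future__ import annotations

import numpy as np

from .alphabet import ALPHABET, N_SYMBOLS, RESIDUE_CLASSES
from .hmm import (
    READS_C_TO_N,
    READS_N_TO_C,
    HmmParameters,
    TOPOLOGY_VERSION,
)

#: Region label -> favoured residue class for the 70/30 initial emissions.
REGION_CLASS_BIAS: dict[str, str] = {
    "tail": "hydrophilic",
    "TMD": "hydrophobic",
    "cap": "basic",
    "globular": "hydrophilic",
    "globular1": "hydrophilic",
    "globular2": "hydrophilic",
    "loop": "hydrophilic",
    "signal_basic": "basic",
    "signal_hydrophobic": "hydrophobic",
    "signal_polar": "hydrophilic",
}

#: Labels that make up the signal-peptide block of the SP/MP models.
SIGNAL_LABELS = ("signal_basic", "signal_hydrophobic", "signal_polar")

_FAVOURED_MASS = 0.7


def initial_emissions(region: str) -> np.ndarray:
    """70/30 class-biased emission row for a region label (linear scale)."""
    try:
        favoured = RESIDUE_CLASSES[REGION_CLASS_BIAS[region]]
    except KeyError:
        raise KeyError(f"unknown region label: {region!r}") from None
    row = np.empty(N_SYMBOLS)
    n_fav = len(favoured)
    for k, letter in enumerate(ALPHABET):
        if letter in favoured:
            row[k] = _FAVOURED_MASS / n_fav
        else:
            row[k] = (1.0 - _FAVOURED_MASS) / (N_SYMBOLS - n_fav)
    return row


class _Builder:
    """Accumulates states and allowed transitions, then normalises."""

    def __init__(self, orientation: str):
        self.orientation = orientation
        self.state_ids: list[str] = []
        self.regions: list[str] = []
        self.succ: list[list[int]] = []
        self.initial: dict[int, float] = {}
        self.emission_rows: list[np.ndarray] = []

    def add_state(self, state_id: str, region: str) -> int:
        self.state_ids.append(state_id)
        self.regions.append(region)
        self.succ.append([])
        self.emission_rows.append(initial_emissions(region))
        return len(self.state_ids) - 1

    def add_block(self, region: str, count: int, prefix: str) -> list[int]:
        return [
            self.add_state(f"{prefix}_{i + 1:02d}", region)
            for i in range(count)
        ]

    def allow(self, i: int, *targets: int) -> None:
        self.succ[i].extend(targets)

    def wire_chain(self, states: list[int], forced: int, exit_state: int) -> None:
        """Linear chain whose first ``forced`` states may only advance;
        later states may advance or exit; the last state must exit.

        A traversal therefore emits between ``forced + 1`` and
        ``len(states)`` residues.
        """
        for k, s in enumerate(states):
            if k < forced:
                self.allow(s, states[k + 1])
            elif k < len(states) - 1:
                self.allow(s, states[k + 1], exit_state)
            else:
                self.allow(s, exit_state)

    def build(self) -> HmmParameters:
        n = len(self.state_ids)
        log_init = np.full(n, -np.inf)
        for i, p in self.initial.items():
            log_init[i] = np.log(p)
        mask = np.zeros((n, n), dtype=bool)
        log_trans = np.full((n, n), -np.inf)
        for i, targets in enumerate(self.succ):
            if not targets:
                raise ValueError(f"state {self.state_ids[i]} has no successor")
            p = 1.0 / len(targets)
            for j in targets:
                mask[i, j] = True
                log_trans[i, j] = np.log(p)
        log_em = np.log(np.vstack(self.emission_rows))
        return HmmParameters(
            state_ids=self.state_ids,
            regions=self.regions,
            log_initial=log_init,
            log_transition=log_trans,
            log_emission=log_em,
            orientation=self.orientation,
            topology_version=TOPOLOGY_VERSION,
            transition_mask=mask,
            initial_mask=np.isfinite(log_init),
        )


def _add_signal_block(b: _Builder) -> list[int]:
    return (
        b.add_block("signal_basic", 10, "sigb")
        + b.add_block("signal_hydrophobic", 15, "sigh")
        + b.add_block("signal_polar", 15, "sigp")
    )


def build_ta_model(tail_state_count: int = 2) -> HmmParameters:
    """Tail-anchored protein model, read from the C-terminus.

    The initial probability is split 0.5/0.5 between the tail's first state
    and the TMD's first state (a TA protein may have no tail at all).  Each
    tail state may loop on itself, advance, or enter the TMD.
    """
    if tail_state_count not in (2, 4):
        raise ValueError("tail_state_count must be 2 or 4")
    b = _Builder(READS_C_TO_N)
    tail = b.add_block("tail", tail_state_count, "tail")
    tmd = b.add_block("TMD", 25, "tmd")
    cap = b.add_block("cap", 5, "cap")
    glob = b.add_state("glob", "globular")
    for k, s in enumerate(tail):
        if k < len(tail) - 1:
            b.allow(s, s, tail[k + 1], tmd[0])
        else:
            b.allow(s, s, tmd[0])
    b.wire_chain(tmd, 14, cap[0])  # decoded TMDs span 15-25 residues
    b.wire_chain(cap, 0, glob)  # decoded caps span 1-5 residues
    b.allow(glob, glob)
    b.initial = {tail[0]: 0.5, tmd[0]: 0.5}
    return b.build()


def build_sp_model() -> HmmParameters:
    """Signal-peptide single-pass model, read from the N-terminus."""
    b = _Builder(READS_N_TO_C)
    sig = _add_signal_block(b)
    glob1 = b.add_state("glob1", "globular1")
    cap = b.add_block("cap", 5, "cap")
    tmd = b.add_block("TMD", 25, "tmd")
    glob2 = b.add_state("glob2", "globular2")
    b.wire_chain(sig, 14, glob1)  # decoded signals span 15-40 residues
    b.allow(glob1, glob1, cap[0])
    b.wire_chain(cap, 0, tmd[0])
    b.wire_chain(tmd, 14, glob2)
    b.allow(glob2, glob2)
    b.initial = {sig[0]: 0.5, glob1: 0.5}
    return b.build()


def build_mp_model() -> HmmParameters:
    """Multi-pass membrane protein model, read from the N-terminus.

    Structure of the signal, globular, cap and TMD regions matches the SP
    model; the TMD exits into the loop region, whose states return to the
    cap (next membrane pass) or the globular state (long connector), so the
    model can thread any number of passes.
    """
    b = _Builder(READS_N_TO_C)
    sig = _add_signal_block(b)
    glob = b.add_state("glob", "globular")
    cap = b.add_block("cap", 5, "cap")
    tmd = b.add_block("TMD", 25, "tmd")
    loop = b.add_block("loop", 20, "loop")
    b.wire_chain(sig, 14, glob)
    b.allow(glob, glob, cap[0])
    b.wire_chain(cap, 0, tmd[0])
    b.wire_chain(tmd, 14, loop[0])
    for k, s in enumerate(loop):  # loops span 1-20 residues
        if k < len(loop) - 1:
            b.allow(s, loop[k + 1], cap[0], glob)
        else:
            b.allow(s, cap[0], glob)
    b.initial = {sig[0]: 0.5, glob: 0.5}
    return b.build()
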