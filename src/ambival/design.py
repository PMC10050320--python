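"""Trial factorial and block/session scheduling for the risk-and-ambiguity choice task.

The task is a series of choices between a sure ±$5 outcome and a lottery whose
outcome probability is either fully known (risk: 25/50/75%) or partially
occluded (ambiguity: 24/50/74% of the probability display hidden, with a 50%
reference probability).  Crossing 6 uncertainty levels with 20 unsigned
magnitudes per domain yields 120 unique gain trials and 120 unique loss trials,
presented once each in 8 single-domain blocks over two scanning sessions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: unsigned lottery magnitudes in dollars (the 20-value menu)
MAGNITUDES: tuple[int, ...] = (
    5, 6, 7, 8, 10, 12, 14, 16, 19, 23, 27, 31, 37, 44, 52, 61, 73, 86, 101, 120,
)
RISK_LEVELS: tuple[float, ...] = (0.25, 0.50, 0.75)
AMBIGUITY_LEVELS: tuple[float, ...] = (0.24, 0.50, 0.74)
#: reference outcome probability of an ambiguous lottery
AMBIGUOUS_P: float = 0.50
SURE_AMOUNT: float = 5.0

DISPLAY_DURATION: float = 6.0   # s, option display (choice/valuation epoch)
RESPONSE_WINDOW: float = 3.5    # s, time limit to register the choice
ITI_MENU: tuple[float, ...] = (4.0, 6.0, 8.0)  # s, jittered inter-trial interval

N_BLOCKS = 8
TRIALS_PER_BLOCK = 30

DESIGN_COLUMNS = ["trial_id", "domain", "uncertainty", "P", "A", "V", "sure_amount", "is_catch"]


def generate_design() -> pd.DataFrame:
    """Generate the full 240-trial factorial design.

    Returns a DataFrame with one row per unique trial and columns
    ``trial_id, domain, uncertainty, P, A, V, sure_amount, is_catch``.
    Ordering of ``trial_id`` is deterministic: domain (gain first), then
    uncertainty (risk first), then P or A ascending, then V ascending.
    Catch trials are those whose lottery magnitude equals the sure amount
    ($5), where one option weakly dominates the other.
    """
    rows = []
    for domain in ("gain", "loss"):
        for p in RISK_LEVELS:
            for v in MAGNITUDES:
                rows.append((domain, "risk", p, 0.0, v))
        for a in AMBIGUITY_LEVELS:
            for v in MAGNITUDES:
                rows.append((domain, "ambiguity", AMBIGUOUS_P, a, v))
    df = pd.DataFrame(rows, columns=["domain", "uncertainty", "P", "A", "V"])
    df.insert(0, "trial_id", np.arange(len(df)))
    df["sure_amount"] = SURE_AMOUNT
    df["is_catch"] = df["V"] == SURE_AMOUNT
    return df


def identify_catch_trials(design: pd.DataFrame) -> pd.DataFrame:
    """Return the catch trials: lottery magnitude equal to the sure amount."""
    return design[design["V"] == SURE_AMOUNT].copy()


@dataclass
class Block:
    """One scan run: 30 trials of a single domain with scheduled onsets."""

    index: int            # 0-based position in the session sequence (0..7)
    session: int          # 1 or 2 (scanning day)
    domain: str           # "gain" or "loss"
    trials: pd.DataFrame  # design columns + onset (s) + iti (s), in presentation order
    n_trs: int            # run duration in TRs (TR = 1 s)


@dataclass
class BlockSchedule:
    """Full two-session schedule: 8 blocks, counterbalance order, seeded jitter."""

    blocks: list[Block]
    order: int
    seed: int
    display_duration: float = DISPLAY_DURATION
    response_window: float = RESPONSE_WINDOW
    iti_menu: tuple[float, ...] = field(default=ITI_MENU)

    def all_trials(self) -> pd.DataFrame:
        """Concatenate trials of all blocks with block/session/run annotation."""
        parts = []
        for b in self.blocks:
            t = b.trials.copy()
            t["block"] = b.index
            t["session"] = b.session
            parts.append(t)
        return pd.concat(parts, ignore_index=True)


def _block_domain_sequence(order: int) -> list[str]:
    """Domain of each of the 8 blocks for a counterbalance order.

    Order 1: day 1 Gain-Gain-Loss-Loss, day 2 Loss-Loss-Gain-Gain.
    Order 2: the reverse.
    """
    seq1 = ["gain", "gain", "loss", "loss", "loss", "loss", "gain", "gain"]
    if order == 1:
        return seq1
    if order == 2:
        return [{"gain": "loss", "loss": "gain"}[d] for d in seq1]
    raise ValueError(f"counterbalance order must be 1 or 2, got {order!r}")


def _stratify_domain(design_domain: pd.DataFrame) -> list[pd.DataFrame]:
    """Split one domain's 120 trials into 4 blocks of 30 (15 risky, 15 ambiguous).

    Trials of each uncertainty type are sorted by magnitude (then uncertainty
    level) and dealt round-robin across the 4 blocks, so every block spans the
    magnitude range and has a comparable subjective-value spread — the per-block
    z-normalisation used downstream implicitly assumes this.
    """
    parts: list[list[pd.DataFrame]] = [[] for _ in range(4)]
    for unc, level_col in (("risk", "P"), ("ambiguity", "A")):
        sub = design_domain[design_domain["uncertainty"] == unc]
        sub = sub.sort_values(["V", level_col], kind="mergesort").reset_index(drop=True)
        for i in range(len(sub)):
            parts[i % 4].append(sub.iloc[[i]])
    return [pd.concat(p, ignore_index=True) for p in parts]


def schedule_blocks(design: pd.DataFrame, order: int, rng_seed: int) -> BlockSchedule:
    """Build the 8-block, two-session schedule with seeded pseudorandomisation.

    Each trial occupies ``display (6 s) + response window (3.5 s) + ITI``; the
    unused part of the response window is folded into the ITI at presentation
    time, so nominal onsets are exact regardless of response time.  ITIs are
    drawn uniformly from {4, 6, 8} s under the seed.  Onsets are the times used
    for GLM modelling (start of option display).
    """
    seq = _block_domain_sequence(order)
    if len(design) != 2 * len(MAGNITUDES) * 6:
        raise ValueError(f"expected the full 240-trial design, got {len(design)} trials")
    rng = np.random.default_rng(rng_seed)

    per_domain = {d: _stratify_domain(design[design["domain"] == d]) for d in ("gain", "loss")}
    counters = {"gain": 0, "loss": 0}
    blocks: list[Block] = []
    for idx, domain in enumerate(seq):
        trials = per_domain[domain][counters[domain]]
        counters[domain] += 1
        perm = rng.permutation(len(trials))
        trials = trials.iloc[perm].reset_index(drop=True)
        itis = rng.choice(ITI_MENU, size=len(trials))
        onsets = np.empty(len(trials))
        t = 0.0
        for i, iti in enumerate(itis):
            onsets[i] = t
            t += DISPLAY_DURATION + RESPONSE_WINDOW + iti
        trials = trials.assign(onset=onsets, iti=itis)
        blocks.append(
            Block(index=idx, session=1 if idx < 4 else 2, domain=domain,
                  trials=trials, n_trs=int(math.ceil(t)))
        )
    return BlockSchedule(blocks=blocks, order=order, seed=rng_seed)


def events_frame(block: Block) -> pd.DataFrame:
    """BIDS-style events table for one run."""
    t = block.trials
    return pd.DataFrame(
        {
            "onset": t["onset"],
            "duration": DISPLAY_DURATION,
            "trial_type": t["uncertainty"].replace({"risk": "risky", "ambiguity": "ambiguous"})
            + "_"
            + t["domain"],
            "trial_id": t["trial_id"],
            "P": t["P"],
            "A": t["A"],
            "V": t["V"],
            "sure_amount": t["sure_amount"],
            "is_catch": t["is_catch"],
        }
    )


def write_events(schedule: BlockSchedule, out_dir) -> list[str]:
    """Write one events TSV per run; returns the written paths."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for b in schedule.blocks:
        p = out / f"ses-{b.session}_run-{b.index + 1}_events.tsv"
        events_frame(b).to_csv(p, sep="\t", index=False)
        paths.append(str(p))
    return paths


def read_events(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
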