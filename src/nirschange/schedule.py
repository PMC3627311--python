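"""Block-design stimulus schedules for the change-detection paradigm.

Sessions alternate *baseline* blocks of a repeated background word (/abuna/)
with *target* blocks in which the background word is pseudo-randomly
interleaved with a contrast word: /abna/ (consonant-cluster condition) or
/abuuna/ (vowel-duration condition).  Tokens are presented at a fixed stimulus
onset asynchrony (SOA, 1.5 s), the target block is fixed-length (9 s infant;
9 or 15 s adult) and baseline blocks are jittered to decorrelate the design
from slow systemic oscillations.

Baseline jitter is quantised to whole SOA multiples so every block holds an
integer number of token slots (a 9-18 s baseline at SOA 1.5 s holds 6-12
tokens).  "Pseudo-random" is made concrete as: within a target block the two
words are near-balanced (counts differ by at most 1) with no run longer than
two of the same word; in multi-token mode the three recorded tokens of a word
cycle without immediate repetition.  Sessions begin and end with a baseline
block, so a schedule with ``n`` target blocks has ``n + 1`` baselines.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "PHONEME_DURATIONS_MS",
    "BASELINE_WORD",
    "CONDITION_WORDS",
    "ScheduleConfig",
    "Block",
    "Token",
    "Schedule",
    "word_duration_ms",
    "generate_infant_schedule",
    "generate_adult_schedule",
    "token_sequence",
    "expected_session_duration_s",
    "INFANT_CONFIG",
    "ADULT_CONDITIONS",
]

#: mean phoneme durations (ms) of the three recorded non-words
PHONEME_DURATIONS_MS: dict[str, tuple[float, ...]] = {
    "abuna": (115.4, 88.8, 128.2, 99.9, 151.8),
    "abna": (112.1, 127.6, 78.1, 140.8),
    "abuuna": (126.3, 88.8, 369.1, 88.3, 150.0),
}

BASELINE_WORD = "abuna"
#: contrast word presented in each target condition
CONDITION_WORDS = {"cluster": "abna", "duration": "abuuna"}


def word_duration_ms(word: str) -> float:
    """Word duration as the sum of its mean phoneme durations (ms)."""
    try:
        return float(sum(PHONEME_DURATIONS_MS[word]))
    except KeyError:
        raise KeyError(f"unknown word {word!r}") from None


@dataclass(frozen=True)
class ScheduleConfig:
    soa_s: float = 1.5
    target_duration_s: float = 9.0
    baseline_jitter_s: tuple[float, float] = (9.0, 18.0)
    n_target_blocks: int = 16
    conditions: tuple[str, ...] = ("cluster", "duration")
    token_mode: str = "multi"  # "single" | "multi"
    tokens_per_word: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.soa_s <= 0:
            raise ValueError("soa must be positive")
        if self.target_duration_s <= 0:
            raise ValueError("target duration must be positive")
        lo, hi = self.baseline_jitter_s
        if lo > hi:
            raise ValueError("baseline jitter interval is empty")
        if self.n_target_blocks < 1:
            raise ValueError("need at least one target block")
        if self.n_target_blocks % len(self.conditions):
            raise ValueError("target-block count must balance the conditions")
        if self.token_mode not in ("single", "multi"):
            raise ValueError(f"unknown token mode {self.token_mode!r}")
        if self._baseline_slot_options().size == 0:
            raise ValueError("baseline jitter interval contains no SOA multiple")

    def _baseline_slot_options(self) -> np.ndarray:
        """Admissible baseline durations: SOA multiples inside the jitter interval."""
        lo, hi = self.baseline_jitter_s
        kmin = int(np.ceil(lo / self.soa_s - 1e-9))
        kmax = int(np.floor(hi / self.soa_s + 1e-9))
        return np.arange(kmin, kmax + 1) * self.soa_s


#: main (infant) experiment defaults
INFANT_CONFIG = ScheduleConfig()

#: the four adult sessions of the 2x2 duration-by-token-variability design
ADULT_CONDITIONS: dict[str, ScheduleConfig] = {
    "short-single": ScheduleConfig(
        target_duration_s=9.0, baseline_jitter_s=(9.0, 18.0),
        n_target_blocks=10, token_mode="single"),
    "long-single": ScheduleConfig(
        target_duration_s=15.0, baseline_jitter_s=(15.0, 22.0),
        n_target_blocks=8, token_mode="single"),
    "short-multi": ScheduleConfig(
        target_duration_s=9.0, baseline_jitter_s=(9.0, 18.0),
        n_target_blocks=10, token_mode="multi"),
    "long-multi": ScheduleConfig(
        target_duration_s=15.0, baseline_jitter_s=(15.0, 22.0),
        n_target_blocks=8, token_mode="multi"),
}


@dataclass(frozen=True)
class Block:
    kind: str  # "baseline" | "target"
    condition: str | None  # None for baseline blocks
    onset_s: float
    duration_s: float

    @property
    def end_s(self) -> float:
        return self.onset_s + self.duration_s


@dataclass(frozen=True)
class Token:
    onset_s: float
    word: str
    token_index: int  # 1..tokens_per_word


@dataclass(frozen=True)
class Schedule:
    config: ScheduleConfig
    blocks: tuple[Block, ...]
    tokens: tuple[Token, ...]

    @property
    def duration_s(self) -> float:
        return float(sum(b.duration_s for b in self.blocks))

    @property
    def target_blocks(self) -> tuple[Block, ...]:
        return tuple(b for b in self.blocks if b.kind == "target")

    def condition_onsets(self, condition: str) -> np.ndarray:
        return np.array(
            [b.onset_s for b in self.blocks
             if b.kind == "target" and b.condition == condition]
        )


def _interleaved_words(n: int, target_word: str, rng: np.random.Generator) -> list[str]:
    """Near-balanced target/background word order with no run longer than 2."""
    n_target = n // 2 + int(rng.integers(0, 2)) if n % 2 else n // 2
    words = [target_word] * n_target + [BASELINE_WORD] * (n - n_target)
    for _ in range(10_000):
        order = rng.permutation(len(words))
        seq = [words[i] for i in order]
        if not any(seq[i] == seq[i + 1] == seq[i + 2] for i in range(len(seq) - 2)):
            return seq
    raise RuntimeError("could not satisfy run-length constraint")  # pragma: no cover


def token_sequence(
    block: Block, config: ScheduleConfig, rng: np.random.Generator
) -> list[Token]:
    """Tokens of one block: onsets spaced exactly SOA apart from block onset.

    Baseline blocks repeat the background word; target blocks interleave the
    condition's contrast word with the background word.  In multi-token mode
    each successive presentation of a word draws one of its recorded tokens
    uniformly, never repeating the immediately preceding token of that word;
    in single mode token index 1 is used throughout.
    """
    n = int(round(block.duration_s / config.soa_s))
    if abs(n * config.soa_s - block.duration_s) > 1e-9:
        raise ValueError("block duration is not a multiple of the SOA")
    if block.kind == "baseline":
        words = [BASELINE_WORD] * n
    else:
        words = _interleaved_words(n, CONDITION_WORDS[block.condition], rng)

    last_index: dict[str, int] = {}
    tokens = []
    for k, word in enumerate(words):
        if config.token_mode == "single":
            idx = 1
        else:
            options = [i for i in range(1, config.tokens_per_word + 1)
                       if i != last_index.get(word)]
            idx = int(rng.choice(options))
            last_index[word] = idx
        tokens.append(Token(onset_s=block.onset_s + k * config.soa_s,
                            word=word, token_index=idx))
    return tokens


def _balanced_condition_order(
    config: ScheduleConfig, rng: np.random.Generator
) -> list[str]:
    per = config.n_target_blocks // len(config.conditions)
    order = [c for c in config.conditions for _ in range(per)]
    return [order[i] for i in rng.permutation(len(order))]


def _generate(config: ScheduleConfig, populate_tokens: bool) -> Schedule:
    rng = np.random.default_rng(config.seed)
    options = config._baseline_slot_options()
    cond_order = _balanced_condition_order(config, rng)

    blocks: list[Block] = []
    t = 0.0
    for cond in cond_order:
        base_dur = float(rng.choice(options))
        blocks.append(Block("baseline", None, t, base_dur))
        t += base_dur
        blocks.append(Block("target", cond, t, config.target_duration_s))
        t += config.target_duration_s
    closing = float(rng.choice(options))
    blocks.append(Block("baseline", None, t, closing))

    tokens: list[Token] = []
    if populate_tokens:
        for block in blocks:
            tokens.extend(token_sequence(block, config, rng))
    return Schedule(config=config, blocks=tuple(blocks), tokens=tuple(tokens))


def generate_infant_schedule(
    config: ScheduleConfig = INFANT_CONFIG,
    *,
    seed: int | None = None,
    populate_tokens: bool = True,
) -> Schedule:
    """Generate a main-experiment session.

    Baseline and target blocks strictly alternate, starting and ending with a
    baseline; the condition sequence is a random permutation with exactly
    equal counts per condition; baseline durations are drawn uniformly from
    the SOA multiples inside the jitter interval.  For the infant design the
    jitter interval may not dip below the target duration.
    """
    if seed is not None:
        config = replace(config, seed=seed)
    if config.baseline_jitter_s[0] < config.target_duration_s:
        raise ValueError(
            "infant design requires baseline jitter lower bound >= target duration"
        )
    return _generate(config, populate_tokens)


def generate_adult_schedule(
    condition: str,
    seed: int = 0,
    *,
    n_target_blocks: int | None = None,
    populate_tokens: bool = True,
) -> Schedule:
    """Generate one adult 2x2 follow-up session.

    ``condition`` is one of ``short-single``, ``long-single``, ``short-multi``,
    ``long-multi`` (target 9 s vs 15 s, single vs multiple tokens per word;
    baselines jittered 9-18 s for short, 15-22 s for long sessions).  Both
    stimulus conditions appear in every session, 4-5 target blocks each, for
    a session of roughly 4-5 minutes.
    """
    try:
        config = ADULT_CONDITIONS[condition]
    except KeyError:
        raise KeyError(f"unknown adult condition {condition!r}") from None
    config = replace(config, seed=seed)
    if n_target_blocks is not None:
        config = replace(config, n_target_blocks=n_target_blocks)
    return _generate(config, populate_tokens)


def expected_session_duration_s(config: ScheduleConfig) -> float:
    """Analytic expected session length: targets plus uniformly drawn baselines."""
    options = config._baseline_slot_options()
    n_base = config.n_target_blocks + 1
    return (
        config.n_target_blocks * config.target_duration_s
        + n_base * float(options.mean())
    )
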