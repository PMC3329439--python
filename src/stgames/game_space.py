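"""Games on the S-T plane and the deterministic memory-one strategy set.

A symmetric 2x2 game is normalized so that mutual cooperation pays ``R = 1``
and mutual defection pays ``P = 0``; the two free parameters are ``S`` (the
sucker's payoff for cooperating against a defector) and ``T`` (the temptation
for defecting against a cooperator).  The four sign combinations of ``S`` and
``T - 1`` carve the plane into the four classic social dilemmas: Harmony,
Snowdrift (Hawk-Dove), Prisoner's Dilemma and Stag Hunt.

A memory-one strategy is described by the probability of cooperating in the
current round given the outcome of the previous one.  Outcomes are indexed by
the focal player's payoff in the previous round, in the fixed global order

    (CC, CD, DC, DD)  <->  payoffs (R, S, T, P)

from the focal player's perspective.  We restrict attention to the 16
deterministic strategies (each intended action is C or D) perturbed by an
implementation error ``eps``: the intended action is executed with probability
``1 - eps``, so every cooperation probability lies strictly inside (0, 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Global state order; index 0..3 = previous-round outcome from the focal view.
STATE_ORDER = ("CC", "CD", "DC", "DD")

#: Permutation mapping the focal player's state index to the opponent's:
#: the opponent sees CD and DC exchanged.
OPPONENT_VIEW = (0, 2, 1, 3)

_CANONICAL_NAMES = {
    "0000": "AllD",
    "1111": "AllC",
    "1001": "Pavlov",
    "1010": "TFT",
    "1000": "GRIM",
}


@dataclass(frozen=True)
class Game:
    """A symmetric 2x2 game with the normalization R = 1, P = 0."""

    S: float
    T: float
    R: float = field(default=1.0, init=False)
    P: float = field(default=0.0, init=False)

    def payoff_vector(self) -> np.ndarray:
        """Payoffs (R, S, T, P) in the (CC, CD, DC, DD) state order."""
        return np.array([self.R, self.S, self.T, self.P], dtype=float)


@dataclass(frozen=True)
class Strategy:
    """A noisy deterministic memory-one strategy.

    Parameters
    ----------
    code
        Four binary digits ``(c_R, c_S, c_T, c_P)``: the intended action after
        receiving payoff R, S, T, P respectively (``1`` = cooperate).
    eps
        Implementation-error probability.  The realized cooperation
        probability is ``1 - eps`` where the code digit is 1 and ``eps``
        where it is 0.
    """

    code: str
    eps: float

    def __post_init__(self):
        validate_code(self.code)
        if not 0.0 <= self.eps < 1.0:
            raise ValueError(f"eps must lie in [0, 1), got {self.eps}")

    @property
    def probs(self) -> np.ndarray:
        """Cooperation probabilities (p_R, p_S, p_T, p_P)."""
        bits = np.array([int(c) for c in self.code], dtype=float)
        return bits * (1.0 - self.eps) + (1.0 - bits) * self.eps

    @property
    def name(self) -> str:
        return canonical_name(self.code)


@dataclass(frozen=True)
class WslsTriple:
    """The three win-stay lose-shift strategies, by decreasing aspiration."""

    ambitious: str
    balanced: str
    modest: str

    def as_tuple(self) -> tuple[str, str, str]:
        return (self.ambitious, self.balanced, self.modest)


def validate_code(code: str) -> str:
    if not (isinstance(code, str) and len(code) == 4 and set(code) <= {"0", "1"}):
        raise ValueError(f"strategy code must be 4 binary digits, got {code!r}")
    return code


def code_of_index(i: int) -> str:
    """Strategy code for index ``i`` in the canonical enumeration order."""
    if not 0 <= i < 16:
        raise ValueError(f"strategy index out of range: {i}")
    return format(i, "04b")


def index_of_code(code: str) -> int:
    """Inverse of :func:`code_of_index`."""
    return int(validate_code(code), 2)


def enumerate_strategies(eps: float) -> list[Strategy]:
    """All 16 noisy deterministic memory-one strategies.

    Order is fixed: code ``0000`` (AllD) through ``1111`` (AllC), i.e. the
    code read as a binary integer equals the list index.  Noiseless
    strategies are excluded because extreme cooperation probabilities are
    unstable against errors, hence ``eps`` must lie strictly inside
    (0, 1/2).
    """
    if not 0.0 < eps < 0.5:
        raise ValueError(f"eps must lie strictly inside (0, 1/2), got {eps}")
    return [Strategy(code_of_index(i), eps) for i in range(16)]


def classify_quadrant(game: Game) -> str:
    """Classify a game by the signs of S and T - 1.

    Returns one of ``Harmony``, ``Snowdrift``, ``PrisonersDilemma``,
    ``StagHunt``, or ``boundary`` when S = 0 or T = 1.
    """
    if game.S == 0.0 or game.T == 1.0:
        return "boundary"
    if game.S > 0.0:
        return "Harmony" if game.T < 1.0 else "Snowdrift"
    return "StagHunt" if game.T < 1.0 else "PrisonersDilemma"


def wsls_strategies(game: Game) -> WslsTriple:
    """Win-stay lose-shift strategies for the three aspiration levels.

    A WSLS player repeats her previous action iff the payoff she just
    obtained exceeds her aspiration level.  With four distinct payoffs there
    are three meaningful aspiration levels, located between consecutive
    payoffs of the descending order.  *Ambitious* is only content with the
    highest payoff, *balanced* with the two highest, *modest* with anything
    but the lowest.

    "Stay" means cooperate again in states CC and CD (own previous action
    was C) and defect again in DC and DD; "shift" is the opposite.  The
    output therefore depends only on the ordering of the payoffs, not their
    values.

    Raises
    ------
    ValueError
        If any two of the four payoffs are equal (degenerate ordering).
    """
    payoffs = game.payoff_vector()
    if len(set(payoffs)) < 4:
        raise ValueError(
            "WSLS strategies require four pairwise distinct payoffs; "
            f"got R={game.R}, S={game.S}, T={game.T}, P={game.P}"
        )
    # A payoff clears the k-th aspiration level iff it ranks among the top k;
    # working with ranks avoids constructing numeric thresholds between
    # payoffs (whose midpoints need not be representable).
    order = np.argsort(-payoffs)
    rank = np.empty(4, dtype=int)
    rank[order] = np.arange(4)  # 0 = highest payoff
    codes = []
    for top in (1, 2, 3):  # ambitious, balanced, modest
        happy = rank < top
        # Own previous action is C in states 0 (CC), 1 (CD); D in 2 (DC), 3 (DD).
        bits = [
            "1" if happy[0] else "0",
            "1" if happy[1] else "0",
            "0" if happy[2] else "1",
            "0" if happy[3] else "1",
        ]
        codes.append("".join(bits))
    return WslsTriple(ambitious=codes[0], balanced=codes[1], modest=codes[2])


def canonical_name(code: str) -> str:
    """Common name of a strategy code (AllD, AllC, Pavlov, TFT, GRIM) or the
    code itself when it has no established name."""
    return _CANONICAL_NAMES.get(validate_code(code), code)
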