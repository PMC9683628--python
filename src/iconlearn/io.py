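"""Session serialization: tidy one-row-per-trial CSV, and a nested JSON mirror.

CSV schema (one row per trial):

    session_id, game_index, complexity, knowledge, trial_index,
    true_rule, choice, stimulus, reward

``game_index`` and ``trial_index`` are 1-based.  Rules are encoded as
``dim:feature`` pairs joined by ``|`` (e.g. ``"0:1|2:0"``); choices as three
comma-separated symbols, one per dimension, with ``-`` marking no selection
(e.g. ``"1,-,2"``); stimuli as three comma-separated feature indices.
Dimension and feature indices are 0-based.  An optional ``latent`` column
carries simulated hypothesis trajectories (``NT`` = not testing).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .task import Configuration, GameSpec, Rule, Session, Stimulus, Trial

CSV_COLUMNS = [
    "session_id",
    "game_index",
    "complexity",
    "knowledge",
    "trial_index",
    "true_rule",
    "choice",
    "stimulus",
    "reward",
]


class SessionDataError(ValueError):
    """Malformed session data; carries per-row messages with line numbers."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__("; ".join(problems))


def encode_rule(rule: Rule) -> str:
    return "|".join(
        f"{d}:{f}" for d, f in enumerate(rule.assignment) if f is not None
    )


def decode_rule(text: str) -> Rule:
    assignment: list[Optional[int]] = [None, None, None]
    for part in text.split("|"):
        d, f = part.split(":")
        assignment[int(d)] = int(f)
    return Rule(tuple(assignment))


def encode_choice(choice: Configuration) -> str:
    return ",".join("-" if f is None else str(f) for f in choice.selection)


def decode_choice(text: str) -> Configuration:
    parts = text.split(",")
    if len(parts) != 3:
        raise ValueError(f"choice must have 3 symbols: {text!r}")
    return Configuration(tuple(None if p == "-" else int(p) for p in parts))


def encode_stimulus(stim: Stimulus) -> str:
    return ",".join(str(f) for f in stim.features)


def decode_stimulus(text: str) -> Stimulus:
    parts = text.split(",")
    if len(parts) != 3:
        raise ValueError(f"stimulus must have 3 features: {text!r}")
    return Stimulus(tuple(int(p) for p in parts))


def sessions_to_frame(sessions: Sequence[Session]) -> pd.DataFrame:
    rows = []
    any_latents = any(s.latents is not None for s in sessions)
    for session in sessions:
        for gi, (spec, trials) in enumerate(session.games, start=1):
            lat = (
                session.latents[gi - 1]
                if session.latents is not None
                else None
            )
            for ti, trial in enumerate(trials, start=1):
                row = {
                    "session_id": session.session_id,
                    "game_index": gi,
                    "complexity": spec.complexity,
                    "knowledge": "known" if spec.known else "unknown",
                    "trial_index": ti,
                    "true_rule": encode_rule(spec.true_rule),
                    "choice": encode_choice(trial.choice),
                    "stimulus": encode_stimulus(trial.stimulus),
                    "reward": trial.reward,
                }
                if any_latents:
                    if lat is None:
                        row["latent"] = ""
                    else:
                        h = lat[ti - 1]
                        row["latent"] = (
                            "NT" if h < 0 else encode_rule(Rule.from_index(h))
                        )
                rows.append(row)
    return pd.DataFrame(rows)


def write_sessions(sessions: Sequence[Session], path) -> None:
    sessions_to_frame(sessions).to_csv(path, index=False)


def frame_to_sessions(df: pd.DataFrame) -> list[Session]:
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise SessionDataError([f"missing columns: {', '.join(missing)}"])
    problems: list[str] = []
    sessions: list[Session] = []
    has_latent = "latent" in df.columns
    for sid, sdf in df.groupby("session_id", sort=False):
        games = []
        latents: list[Optional[list[int]]] = []
        for gi, gdf in sdf.groupby("game_index", sort=True):
            spec = None
            trials: list[Trial] = []
            lat: list[int] = []
            for row in gdf.itertuples():
                line = row.Index + 2  # header + 0-based index
                try:
                    rule = decode_rule(row.true_rule)
                    choice = decode_choice(row.choice)
                    stim = decode_stimulus(row.stimulus)
                    trial = Trial(choice, stim, int(row.reward))
                    if spec is None:
                        known = {"known": True, "unknown": False}[row.knowledge]
                        spec = GameSpec(
                            int(row.complexity), known, rule,
                            n_trials=len(gdf),
                        )
                    if has_latent:
                        val = row.latent
                        lat.append(
                            -1
                            if (val == "NT" or pd.isna(val) or val == "")
                            else decode_rule(str(val)).index
                        )
                except (ValueError, KeyError) as exc:
                    problems.append(f"line {line}: {exc}")
                    continue
                trials.append(trial)
            if spec is not None:
                games.append((spec, trials))
                latents.append(lat if has_latent and lat else None)
        sessions.append(
            Session(
                games,
                session_id=str(sid),
                latents=latents if any(l is not None for l in latents) else None,
            )
        )
    if problems:
        raise SessionDataError(problems)
    return sessions


def read_sessions(path) -> list[Session]:
    """Read and validate a tidy session CSV; empty files yield an empty list."""
    df = pd.read_csv(path, dtype={"latent": str}, keep_default_na=False)
    if df.empty and set(CSV_COLUMNS).issubset(df.columns):
        return []
    return frame_to_sessions(df)


# ---------------------------------------------------------------------------
# JSON mirror
# ---------------------------------------------------------------------------


def sessions_to_json(sessions: Sequence[Session]) -> dict:
    out = []
    for session in sessions:
        games = []
        for gi, (spec, trials) in enumerate(session.games):
            game = {
                "complexity": spec.complexity,
                "knowledge": "known" if spec.known else "unknown",
                "true_rule": encode_rule(spec.true_rule),
                "trials": [
                    {
                        "choice": encode_choice(t.choice),
                        "stimulus": encode_stimulus(t.stimulus),
                        "reward": t.reward,
                    }
                    for t in trials
                ],
            }
            if session.latents is not None and session.latents[gi] is not None:
                game["latent"] = [
                    "NT" if h < 0 else encode_rule(Rule.from_index(h))
                    for h in session.latents[gi]
                ]
            games.append(game)
        out.append({"session_id": session.session_id, "games": games})
    return {"sessions": out}


def write_sessions_json(sessions: Sequence[Session], path) -> None:
    Path(path).write_text(json.dumps(sessions_to_json(sessions), indent=1))


def read_sessions_json(path) -> list[Session]:
    data = json.loads(Path(path).read_text())
    sessions = []
    for s in data["sessions"]:
        games, latents = [], []
        for g in s["games"]:
            rule = decode_rule(g["true_rule"])
            trials = [
                Trial(
                    decode_choice(t["choice"]),
                    decode_stimulus(t["stimulus"]),
                    int(t["reward"]),
                )
                for t in g["trials"]
            ]
            spec = GameSpec(
                int(g["complexity"]),
                g["knowledge"] == "known",
                rule,
                n_trials=len(trials),
            )
            games.append((spec, trials))
            latents.append(
                [
                    -1 if h == "NT" else decode_rule(h).index
                    for h in g["latent"]
                ]
                if "latent" in g
                else None
            )
        sessions.append(
            Session(
                games,
                session_id=s["session_id"],
                latents=latents if any(l is not None for l in latents) else None,
            )
        )
    return sessions
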