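"""Categorized motivational-message templates and slot-filled rendering.

Each template belongs to one of the engine's 15 categories and one of three
persuasion types: gain-framed (benefits of acting), loss-framed (costs of not
acting) or self-efficacy (belief in one's own capability).  Template bodies
carry named slots in single curly braces — ``{poi_name}``, ``{steps_remaining}``
— that are filled from the decision context at send time.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from datetime import datetime
from importlib import resources
from pathlib import Path
from typing import IO, Iterable, Optional, Union

import numpy as np

from .engine import CATEGORIES, DecisionContext, InterventionDecision

MESSAGE_TYPES = ("gain_framed", "loss_framed", "self_efficacy")

#: Slots a template body may reference.
SLOT_VOCABULARY = frozenset(
    {
        "poi_name",
        "poi_kind",
        "distance_m",
        "minutes_to_lunch",
        "minutes_to_endofwork",
        "steps_today",
        "step_goal",
        "steps_remaining",
        "temperature_c",
    }
)

_SLOT_RE = re.compile(r"\{([^{}]*)\}")
_POI_SLOTS = {"poi_name", "poi_kind", "distance_m"}


class BankLoadError(ValueError):
    pass


class RenderError(ValueError):
    pass


class SelectionError(LookupError):
    pass


@dataclass(frozen=True)
class MessageTemplate:
    template_id: str
    category_id: str
    msg_type: str
    heading: str
    body: str

    def slots(self) -> frozenset[str]:
        return frozenset(_SLOT_RE.findall(self.body) + _SLOT_RE.findall(self.heading))


@dataclass(frozen=True)
class RenderedMessage:
    template_id: str
    category_id: str
    msg_type: str
    heading: str
    body: str
    sent_at: datetime


def _validate(tpl: MessageTemplate) -> None:
    if tpl.category_id not in CATEGORIES:
        raise BankLoadError(f"template {tpl.template_id}: unknown category {tpl.category_id!r}")
    if tpl.msg_type not in MESSAGE_TYPES:
        raise BankLoadError(f"template {tpl.template_id}: unknown msg_type {tpl.msg_type!r}")
    for text in (tpl.heading, tpl.body):
        for slot in _SLOT_RE.findall(text):
            if slot not in SLOT_VOCABULARY:
                raise BankLoadError(
                    f"template {tpl.template_id}: unknown slot {{{slot}}}"
                )
        # an unbalanced brace is malformed slot syntax
        if text.count("{") != text.count("}"):
            raise BankLoadError(f"template {tpl.template_id}: unbalanced braces")


def load_bank(source: Union[str, Path, IO[str], None] = None) -> list[MessageTemplate]:
    """Load and validate a template bank (JSON array of template objects).

    With no argument, loads the bundled default bank.  Every category must be
    covered by at least one template of each message type.
    """
    if source is None:
        text = resources.files("deskbreak.data").joinpath("message_bank.json").read_text()
    elif hasattr(source, "read"):
        text = source.read()
    else:
        text = Path(source).read_text()
    try:
        raw = json.loads(text)
    except json.JSONDecodeError as exc:
        raise BankLoadError(f"malformed bank JSON: {exc}") from exc
    if not isinstance(raw, list) or not raw:
        raise BankLoadError("template bank is empty")
    bank = [MessageTemplate(**item) for item in raw]
    for tpl in bank:
        _validate(tpl)
    seen = {(t.category_id, t.msg_type) for t in bank}
    missing = [
        (c, m) for c in CATEGORIES for m in MESSAGE_TYPES if (c, m) not in seen
    ]
    if missing:
        raise BankLoadError(f"bank missing category/type combinations: {missing[:5]}")
    return bank


def save_bank(bank: Iterable[MessageTemplate], path: Union[str, Path]) -> None:
    rows = [
        {
            "template_id": t.template_id,
            "category_id": t.category_id,
            "msg_type": t.msg_type,
            "heading": t.heading,
            "body": t.body,
        }
        for t in bank
    ]
    Path(path).write_text(json.dumps(rows, indent=1))


def pick_template(
    bank: Iterable[MessageTemplate],
    category_id: str,
    rng: np.random.Generator,
) -> MessageTemplate:
    """Uniform seeded draw among the category's templates."""
    candidates = [t for t in bank if t.category_id == category_id]
    if not candidates:
        raise SelectionError(f"no templates for category {category_id!r}")
    return candidates[int(rng.integers(len(candidates)))]


def _slot_values(ctx: DecisionContext, decision: InterventionDecision) -> dict[str, str]:
    values: dict[str, str] = {
        "steps_today": str(int(ctx.steps_today)),
        "step_goal": str(int(ctx.step_goal)),
        "steps_remaining": str(max(0, int(ctx.step_goal) - int(ctx.steps_today))),
        "temperature_c": str(int(round(ctx.weather.temperature))),
    }
    now_min = ctx.now.hour * 60 + ctx.now.minute
    lunch = ctx.schedule.lunch_start.hour * 60 + ctx.schedule.lunch_start.minute
    endwork = ctx.schedule.work_end.hour * 60 + ctx.schedule.work_end.minute
    values["minutes_to_lunch"] = str(max(0, lunch - now_min))
    values["minutes_to_endofwork"] = str(max(0, endwork - now_min))
    if decision.eligible_pois:
        from .engine import haversine_m  # local import avoids cycle at module load

        # prefer the destination kind the category implies (e.g. a park for
        # afterwork-park); eligible_pois is already sorted nearest-first
        kind_hint = {
            "afterwork-park": "park",
            "afterwork-gym": "gym",
            "afterwork-mall": "mall",
            "lunch-walk-out": "restaurant",
        }.get(decision.category_id or "")
        nearest = next(
            (p for p in decision.eligible_pois if p.kind == kind_hint),
            decision.eligible_pois[0],
        )
        values["poi_name"] = nearest.name
        values["poi_kind"] = nearest.kind
        values["distance_m"] = str(int(round(haversine_m(ctx.user_location, nearest.location))))
    return values


def render(
    template: MessageTemplate,
    ctx: DecisionContext,
    decision: InterventionDecision,
) -> RenderedMessage:
    """Fill the template's slots from the context; deterministic.

    Raises :class:`RenderError` if a slot cannot be resolved (a POI slot with
    no eligible POI); the caller should fall back to a POI-free template.
    """
    values = _slot_values(ctx, decision)

    def fill(text: str) -> str:
        def sub(match: re.Match[str]) -> str:
            slot = match.group(1)
            if slot not in values:
                if slot in _POI_SLOTS:
                    raise RenderError(
                        f"template {template.template_id}: slot {{{slot}}} "
                        "unresolvable with no eligible POI"
                    )
                raise RenderError(f"template {template.template_id}: unresolvable slot {{{slot}}}")
            return values[slot]

        return _SLOT_RE.sub(sub, text)

    return RenderedMessage(
        template_id=template.template_id,
        category_id=template.category_id,
        msg_type=template.msg_type,
        heading=fill(template.heading),
        body=fill(template.body),
        sent_at=ctx.now,
    )


def poi_free_templates(bank: Iterable[MessageTemplate], category_id: str) -> list[MessageTemplate]:
    """Templates of a category that use no POI slots (safe with empty POI lists)."""
    return [
        t for t in bank if t.category_id == category_id and not (t.slots() & _POI_SLOTS)
    ]
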