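"""Minimal structural validator for the pipeline report schema.

Supports the subset of JSON-Schema keywords the report schema uses:
``type``, ``properties``, ``required``, ``items``, ``additionalProperties``
(boolean form). Numbers accept ints where ``number`` is declared; ``null``
is accepted wherever a type list includes it.
"""

from __future__ import annotations

_TYPE_MAP = {
    "object": dict,
    "array": list,
    "string": str,
    "boolean": bool,
    "integer": int,
    "null": type(None),
}


class SchemaError(ValueError):
    pass


def _check_type(value, expected: str, path: str) -> None:
    if expected == "number":
        ok = isinstance(value, (int, float)) and not isinstance(value, bool)
    elif expected == "integer":
        ok = isinstance(value, int) and not isinstance(value, bool)
    else:
        ok = isinstance(value, _TYPE_MAP[expected])
    if not ok:
        raise SchemaError(f"{path}: expected {expected}, got {type(value).__name__}")


def validate(instance, schema: dict, path: str = "$") -> None:
    """Raise :class:`SchemaError` if ``instance`` violates ``schema``."""
    expected = schema.get("type")
    if expected is not None:
        types = expected if isinstance(expected, list) else [expected]
        errors = []
        for t in types:
            try:
                _check_type(instance, t, path)
                break
            except SchemaError as exc:
                errors.append(exc)
        else:
            raise errors[0]
        if instance is None and "null" in types:
            return
    if isinstance(instance, dict):
        for key in schema.get("required", []):
            if key not in instance:
                raise SchemaError(f"{path}: missing required key {key!r}")
        props = schema.get("properties", {})
        for key, sub in props.items():
            if key in instance:
                validate(instance[key], sub, f"{path}.{key}")
        if schema.get("additionalProperties") is False:
            extra = set(instance) - set(props)
            if extra:
                raise SchemaError(f"{path}: unexpected keys {sorted(extra)}")
    if isinstance(instance, list) and "items" in schema:
        for i, item in enumerate(instance):
            validate(item, schema["items"], f"{path}[{i}]")
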