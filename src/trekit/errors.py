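"""Exception hierarchy shared across the toolkit."""


class TrekitError(Exception):
    """Base class for all toolkit errors."""


class SchemaError(TrekitError):
    """A table, column or dialect mapping does not resolve against the logical schema."""


class IntegrityError(TrekitError):
    """A database invariant (unique patients, referential integrity, parseable dates) is violated."""


class DefinitionError(TrekitError):
    """A dataset definition is ill-formed: domain mismatch, dtype error, missing sort keys."""


class SerializationError(TrekitError):
    """A serialized dataset definition cannot be parsed or resolved."""

    def __init__(self, message: str, location: str | None = None):
        self.location = location
        super().__init__(message if location is None else f"{message} (at {location})")


class GenerationError(TrekitError):
    """Dummy-data generation could not satisfy its constraints."""


class CodelistError(TrekitError):
    """A codelist file or operation is invalid (duplicate codes, system mismatch, pending decisions)."""


class ProjectError(TrekitError):
    """A project pipeline fails validation; carries the complete list of failures."""

    def __init__(self, failures: list[str]):
        self.failures = list(failures)
        super().__init__("; ".join(self.failures))


class ExecutorError(TrekitError):
    """An action could not be executed: missing executor, undeclared input/output, nonzero exit."""


class ReleaseError(TrekitError):
    """A file may not be released: wrong sensitivity level, undeclared, or stale."""
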