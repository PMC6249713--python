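"""Exception hierarchy. User-facing errors derive from BacnerError so the CLI
can map them to exit code 1; anything else is an internal error (exit 2)."""


class BacnerError(Exception):
    """Base class for all user-facing errors."""


class ParseError(BacnerError):
    """Malformed corpus, template, or model file."""


class ConfigError(BacnerError):
    """Invalid parameter or configuration value."""


class PipelineError(BacnerError):
    """A batch-prediction chunk failed; message names the chunk."""
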