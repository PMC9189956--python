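"""Minimal scikit-learn-compatible parameter plumbing.

Provides ``get_params``/``set_params`` with the exact semantics sklearn's
``BaseEstimator`` implements (introspection of ``__init__`` keywords), so
the package's estimators can be cloned and used inside sklearn pipelines
and model-selection utilities without importing scikit-learn.
"""

from __future__ import annotations

import inspect


class ParamsMixin:
    @classmethod
    def _param_names(cls) -> list[str]:
        sig = inspect.signature(cls.__init__)
        return [
            name
            for name, p in sig.parameters.items()
            if name != "self" and p.kind not in (p.VAR_POSITIONAL, p.VAR_KEYWORD)
        ]

    def get_params(self, deep: bool = True) -> dict:
        return {name: getattr(self, name) for name in self._param_names()}

    def set_params(self, **params):
        valid = set(self._param_names())
        for key, value in params.items():
            if key not in valid:
                raise ValueError(
                    f"invalid parameter {key!r} for estimator {type(self).__name__}"
                )
            setattr(self, key, value)
        return self

    def __repr__(self) -> str:
        args = ", ".join(f"{k}={v!r}" for k, v in self.get_params().items())
        return f"{type(self).__name__}({args})"
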