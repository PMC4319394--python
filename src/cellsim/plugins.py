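"""Plugin registry: the modularity backbone.

Features register as in-package plugin descriptors with a category,
selectability, CLI capability and dependencies; "loading" a plugin means
activating its registration.  Selectable plugins are chosen by the user;
non-selectable ones load exactly when some selected plugin (transitively)
depends on them.  Resolution is pure: the same inputs always give the same
load order and statuses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Tuple

from .errors import DependencyCycleError, RegistryError

CATEGORIES = ("api", "editing", "simulation", "solver", "data-store",
              "miscellaneous", "organisation")


@dataclass(frozen=True)
class PluginDescriptor:
    name: str
    category: str
    selectable: bool = True
    cli_capable: bool = False
    dependencies: Tuple[str, ...] = ()
    status: str = "loaded"      # loaded | unloadable | missing-dependency
    #: registration hook; a hook that raises marks the plugin unloadable
    loader: Optional[object] = field(default=None, compare=False)


def shipped_plugins() -> List[PluginDescriptor]:
    """The default plugin table, mirroring the package's own architecture.

    ``CellMLTools`` (validation + the export machinery) is the only
    CLI-capable plugin in the shipped configuration.
    """
    d = PluginDescriptor
    return [
        d("Core", "miscellaneous", selectable=False),
        d("CellMLSupport", "api", selectable=False,
          dependencies=("Core",)),
        d("CellMLTools", "miscellaneous", selectable=True, cli_capable=True,
          dependencies=("CellMLSupport",)),
        d("CellMLAnnotation", "editing", selectable=True,
          dependencies=("CellMLSupport",)),
        d("DataStore", "api", selectable=False, dependencies=("Core",)),
        d("CSVDataStore", "data-store", selectable=True,
          dependencies=("DataStore",)),
        d("ForwardEuler", "solver", selectable=True,
          dependencies=("Core",)),
        d("Heun", "solver", selectable=True, dependencies=("Core",)),
        d("SecondOrderRungeKutta", "solver", selectable=True,
          dependencies=("Core",)),
        d("FourthOrderRungeKutta", "solver", selectable=True,
          dependencies=("Core",)),
        d("AdaptiveODE", "solver", selectable=True,
          dependencies=("Core",)),
        d("BackwardEuler", "solver", selectable=True,
          dependencies=("Core",)),
        d("NewtonNLA", "solver", selectable=True, dependencies=("Core",)),
        d("SingleCellSimulation", "simulation", selectable=True,
          dependencies=("CellMLSupport", "DataStore", "NewtonNLA")),
    ]

#: plugins active regardless of selection
ALWAYS_ON = ("Core",)


def resolve_plugins(descriptors: Iterable[PluginDescriptor],
                    selected: Optional[Iterable[str]] = None,
                    disabled: Iterable[str] = ()
                    ) -> Tuple[List[str], Dict[str, str]]:
    """Compute the load order and per-plugin statuses.

    ``selected`` defaults to every selectable plugin.  Returns
    ``(load_order, statuses)``: the order is a topological order of the
    selected closure (dependencies first, name-sorted among ties); statuses
    cover every descriptor.
    """
    by_name = {}
    for d in descriptors:
        if d.name in by_name:
            raise RegistryError(f"plugin {d.name!r} registered twice")
        by_name[d.name] = d
    disabled = set(disabled)
    if selected is None:
        selected = [d.name for d in by_name.values()
                    if d.selectable and d.name not in disabled]
    else:
        for name in selected:
            if name not in by_name:
                raise RegistryError(f"unknown plugin {name!r}")

    _check_cycles(by_name)

    # statuses reflect loadability, independent of selection
    statuses: Dict[str, str] = {}

    def loadable(name: str, trail=()) -> bool:
        if name in statuses:
            return statuses[name] == "loaded"
        d = by_name.get(name)
        if d is None or name in disabled:
            return False
        ok = all(loadable(dep, trail + (name,)) for dep in d.dependencies)
        if not ok:
            statuses[name] = "missing-dependency"
            return False
        if d.loader is not None:
            try:
                d.loader()
            except Exception:
                statuses[name] = "unloadable"
                return False
        statuses[name] = "loaded"
        return True

    for name in sorted(by_name):
        loadable(name)

    # selected closure in dependency order
    order: List[str] = []
    visiting: set = set()

    def visit(name: str):
        if name in order or name in disabled or name not in by_name:
            return
        if statuses.get(name) != "loaded":
            return
        visiting.add(name)
        for dep in sorted(by_name[name].dependencies):
            visit(dep)
        visiting.discard(name)
        order.append(name)

    for name in ALWAYS_ON:
        if name in by_name:
            visit(name)
    for name in sorted(selected):
        visit(name)
    return order, statuses


def _check_cycles(by_name: Dict[str, PluginDescriptor]):
    WHITE, GREY, BLACK = 0, 1, 2
    color = {name: WHITE for name in by_name}
    stack: List[str] = []

    def dfs(name: str):
        color[name] = GREY
        stack.append(name)
        for dep in by_name[name].dependencies:
            if dep not in by_name:
                continue
            if color[dep] == GREY:
                cycle = stack[stack.index(dep):] + [dep]
                raise DependencyCycleError(cycle)
            if color[dep] == WHITE:
                dfs(dep)
        stack.pop()
        color[name] = BLACK

    for name in sorted(by_name):
        if color[name] == WHITE:
            dfs(name)


class PluginRegistry:
    """Mutable view over a descriptor table with enable/disable switches."""

    def __init__(self, descriptors: Optional[List[PluginDescriptor]] = None):
        self.descriptors = list(descriptors if descriptors is not None
                                else shipped_plugins())
        self.disabled: set = set()

    def disable(self, name: str):
        if not any(d.name == name for d in self.descriptors):
            raise RegistryError(f"unknown plugin {name!r}")
        self.disabled.add(name)

    def enable(self, name: str):
        self.disabled.discard(name)

    def resolve(self, selected=None):
        return resolve_plugins(self.descriptors, selected,
                               disabled=self.disabled)

    def cli_plugins(self) -> List[str]:
        """Name-sorted CLI-capable plugins that currently load."""
        _, statuses = self.resolve()
        return sorted(d.name for d in self.descriptors
                      if d.cli_capable and statuses[d.name] == "loaded")

    def cli_status(self) -> List[str]:
        """One ``name: status`` line per descriptor, name-sorted."""
        _, statuses = self.resolve()
        return [f"{name}: {statuses[name]}" for name in sorted(statuses)]


def cli_plugins(registry: PluginRegistry) -> List[str]:
    return registry.cli_plugins()


def cli_status(registry: PluginRegistry) -> List[str]:
    return registry.cli_status()
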