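# stpbn

Semi-tensor-product analysis of synchronous Boolean networks: algebraic
transition matrices, reachability classification on the time-transition
diagram, exhaustive enumeration of reachable 2-node networks, state-feedback
control synthesis, and trajectory simulation.

## The problem

Boolean networks model gene regulation as discrete-time dynamics: each node
(gene/protein) holds 0 or 1 and updates synchronously through a logical
function of the current state. Two questions drive experiment design on such
models: *which joint states can the system be driven into by only changing
the initial condition* (reachability), and *what feedback input makes every
state attainable* (control).

`stpbn` answers both with the semi-tensor product (STP) formalism. A Boolean
value is the basis vector e₂¹ = (1,0)ᵀ (true) or e₂² = (0,1)ᵀ (false); the
joint state of n nodes is the STP of the per-node vectors, a basis vector
e_{2ⁿ}ʲ (all-ones ↦ j = 1, all-zeros ↦ j = 2ⁿ). Every logical function f has
a 2×2ᵏ structure matrix M with f(x₁..x_k) = M ⋉ x₁ ⋉ … ⋉ x_k, where

    A ⋉ B = (A ⊗ I_{α/n})(B ⊗ I_{α/p}),   α = lcm(n, p),

and the whole network has a unique 2ⁿ×2ⁿ transition matrix L with
x(k+1) = L ⋉ x(k), computable either by direct state enumeration or by the
algebraic product Lₙ = M₁ ⋉ ∏ᵢ₌₂ⁿ [(I_{2ⁿ} ⊗ Mᵢ) ⋉ Φₙ] with the
power-reducing matrix Φₙ (x ⋉ x = Φₙ ⋉ x). Both routes are implemented and
must agree.

Key results the package operationalizes:

* **Reachability test.** A network is reachable iff its transition diagram
  is one directed cycle through all 2ⁿ states — L is a full-cycle
  permutation with zero diagonal and (for n ≥ 2) no 2-cycles. With a unique
  attractor, the reachable states are exactly the attractor cycle; with
  several attractors, none.
* **Six simplest 2-node forms.** Of all 256 structure-matrix combinations,
  exactly six distinct reachable transition matrices survive; they pair up
  under swapping x₁ ↔ x₂.
* **Feedback synthesis by block doubling.** Extending a reachable n-node
  base by one controlled node doubles each nonzero cell of L into a 2×2
  identity or skew block; the extension is reachable iff the skew count is
  odd, and the controlled node's minimized truth table *is* the feedback law
  u.

## Worked example: the p53 switch

The bundled four-gene network (`x₁..x₄` = ATM, p53, Wip1, Mdm2) is

    ATM  = !Wip1
    p53  = ATM & !Mdm2
    Wip1 = p53
    Mdm2 = !ATM & (p53 | Wip1)

```bash
$ stpbn matrix src/stpbn/data/p53.bn
nodes: ATM, p53, Wip1, Mdm2
L = (e_16^14, e_16^10, e_16^6, e_16^2, e_16^16, e_16^12, e_16^8, e_16^4, e_16^13, e_16^13, e_16^5, e_16^5, e_16^15, e_16^15, e_16^8, e_16^8)

$ stpbn reach src/stpbn/data/p53.bn
not reachable
reachable states (6): 2, 4, 8, 10, 13, 15
non-reachable states (10): 1, 3, 5, 6, 7, 9, 11, 12, 14, 16
attractors: (2 -> 10 -> 13 -> 15 -> 8 -> 4)
failed matrix properties: permutation
```

Column j of L is the one-step successor of integrated state j: the all-ones
state e₁₆¹ steps to e₁₆¹⁴, and e₁₆⁸ (ATM high, the rest low) steps to e₁₆⁴.
The unique attractor is the 6-cycle 8 → 4 → 2 → 10 → 13 → 15 → 8: a stable
period-6 expression pulse. Only those six states are reachable by changing
initial conditions; trajectories from the other ten show a transient phase
first (`stpbn simulate src/stpbn/data/p53.bn --initial 1 --csv pulses.csv`
writes the per-gene 0/1 time course).

Feedback synthesis on the lower-triangle 3-node template (reachable 2-node
base x₁' = ¬x₂, x₂' = x₁ plus a controlled third node x₃' = u):

```bash
$ stpbn control src/stpbn/data/three_node_control.bn
u = !x1 & !x2 & !x3 | x1 & x3 | x2 & x3
closed-loop L = (e_8^5, e_8^6, e_8^1, e_8^2, e_8^7, e_8^8, e_8^4, e_8^3)
closed loop verified reachable (single full-length cycle)
```

The synthesized law u makes the closed loop a single 8-cycle, so every joint
state of the 3-node network becomes reachable. `stpbn enumerate2` prints the
six simplest reachable 2-node forms with their minimized dynamics and swap
partners.

The same functionality is available as a library (`stpbn.semi_tensor_product`,
`stpbn.transition_matrix_stp`, `stpbn.classify_states`,
`stpbn.synthesize_feedback_control`, ...); see `docs/methods.md` for the
modelling details.

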