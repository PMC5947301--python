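"""State initialization, one-step tests, and the closed reaching loop."""

import numpy as np
import pytest

import babblereach as br
from babblereach.coding import decode_activations
from babblereach.networks import forward_step, inverse_step


class TestInitializeState:
    def test_zero_weights_settle_at_half(self, grids):
        motor, visual = grids
        params = br.ModelParams.initialize(
            br.LayerSizes(), np.random.default_rng(0), scale=0.0
        )
        h = br.initialize_state(params, motor, visual, br.HandPosition(1.0, 0.0), n=7)
        assert np.allclose(h, 0.5)

    def test_trained_state_settles(self, scaled_models):
        # with frozen inputs the recurrence contracts: the step-to-step
        # change at n=20 is far below the change at n=2
        cfg, params, _ = scaled_models[0]
        motor, visual = br.grids_from_config(cfg)
        y = visual.activations((1.0, 0.0))
        u = motor.activations((0.0, 0.0))
        h = br.initial_state(params.sizes, params.dtype)
        deltas = []
        for _ in range(20):
            h_new, _ = forward_step(params, u, y, h)
            deltas.append(np.max(np.abs(h_new - h)))
            h = h_new
        assert deltas[19] < deltas[1] / 10.0


class TestOneStepTests:
    def test_zero_command_leaves_actual_at_initial(self, grids):
        params = br.ModelParams.initialize(
            br.LayerSizes(), np.random.default_rng(1), scale=0.05
        )
        initial = br.ArmConfig(30.0, 60.0)
        res = br.test_forward(
            params, *grids, initial=initial, commands=[br.MotorCommand(0.0, 0.0)]
        )
        (_, actual, _), = res
        pos0 = br.forward_kinematics(initial)
        assert actual.r == pytest.approx(pos0.r) and actual.theta == pytest.approx(pos0.theta)

    def test_grids_produce_25_pairs(self, grids):
        params = br.ModelParams.initialize(
            br.LayerSizes(), np.random.default_rng(1), scale=0.05
        )
        assert len(br.test_forward(params, *grids)) == 25
        assert len(br.test_inverse(params, *grids)) == 25

    def test_forward_interior_beats_edge(self, scaled_models):
        # predictions are least accurate for commands at the range limits
        passes = 0
        for cfg, params, _ in scaled_models:
            motor, visual = br.grids_from_config(cfg)
            res = br.test_forward(params, motor, visual)
            interior, edge = [], []
            for cmd, actual, pred in res:
                err = np.hypot(pred.x - actual.x, pred.y - actual.y)
                at_edge = abs(cmd.d_alpha) == 20.0 or abs(cmd.d_beta) == 20.0
                (edge if at_edge else interior).append(err)
            passes += np.mean(interior) < np.mean(edge)
        assert passes >= 2

    def test_inverse_self_target_commands_small(self, scaled_models):
        # asking for the current hand position should elicit a near-zero command
        passes = 0
        for cfg, params, _ in scaled_models:
            motor, visual = br.grids_from_config(cfg)
            initial = br.ArmConfig(30.0, 60.0)
            pos0 = br.forward_kinematics(initial)
            (_, cmd), = br.test_inverse(
                params, motor, visual, initial=initial, targets=[pos0]
            )
            passes += abs(cmd.d_alpha) < 10.0 and abs(cmd.d_beta) < 10.0
        assert passes >= 2

    def test_inverse_commands_move_hand_toward_targets(self, scaled_models):
        passes = 0
        for cfg, params, _ in scaled_models:
            motor, visual = br.grids_from_config(cfg)
            initial = br.ArmConfig(30.0, 60.0)
            pos0 = br.forward_kinematics(initial)
            closer = 0
            for target, cmd in br.test_inverse(params, motor, visual, initial=initial):
                d0 = np.hypot(target.x - pos0.x, target.y - pos0.y)
                if d0 < 1e-9:
                    closer += 1  # the self-target cannot get closer
                    continue
                moved = br.forward_kinematics(br.apply_command(initial, cmd))
                closer += np.hypot(target.x - moved.x, target.y - moved.y) < d0
            passes += closer >= 20
        assert passes >= 2


class TestReachLoop:
    def _any_params(self):
        return br.ModelParams.initialize(
            br.LayerSizes(), np.random.default_rng(2), scale=0.05
        )

    def test_zero_loops_yields_only_initial_posture(self, grids):
        spec = br.ReachSpec(target=br.HandPosition(2.0, 0.0), n_loop=0)
        traj = br.reach(self._any_params(), *grids, spec)
        assert len(traj.steps) == 1
        assert traj.steps[0].config == spec.initial_posture

    def test_trajectory_consistency(self, grids):
        # re-applying the recorded commands reproduces the recorded postures
        spec = br.ReachSpec(target=br.HandPosition(2.0, 30.0), n_loop=5)
        traj = br.reach(self._any_params(), *grids, spec)
        config = spec.initial_posture
        for step in traj.steps[1:]:
            config = br.apply_command(config, step.command)
            assert step.config == config

    def test_hand_vision_never_enters_the_loop(self, grids):
        # oracle: recompute the command sequence from the weights alone,
        # without ever touching the arm or its hand position
        motor, visual = grids
        params = self._any_params()
        spec = br.ReachSpec(target=br.HandPosition(2.0, -60.0), n_loop=6)
        traj = br.reach(params, motor, visual, spec)

        pos0 = br.forward_kinematics(spec.initial_posture)
        h = br.initialize_state(params, motor, visual, pos0, spec.init_iterations)
        t_act = visual.activations(spec.target.as_array())
        for step in traj.steps[1:]:
            u_post = inverse_step(params, t_act, h)
            dec = decode_activations(np.asarray(u_post, dtype=float), motor)
            assert step.command.d_alpha == dec[0]
            assert step.command.d_beta == dec[1]
            h, _ = forward_step(params, u_post, None, h)

    def test_reencode_mode_differs_but_stays_valid(self, scaled_models):
        cfg, params, _ = scaled_models[0]
        motor, visual = br.grids_from_config(cfg)
        spec = br.ReachSpec(target=br.HandPosition(2.0, 30.0), n_loop=4)
        a = br.reach(params, motor, visual, spec, reencode_motor=False)
        b = br.reach(params, motor, visual, spec, reencode_motor=True)
        assert len(a.steps) == len(b.steps) == 5
        assert a.steps[-1].config != b.steps[-1].config

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            br.ReachSpec(target=br.HandPosition(2.0, 0.0), n_loop=-1)
        with pytest.raises(ValueError):
            br.ReachSpec(target=br.HandPosition(2.0, 0.0), init_iterations=0)
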