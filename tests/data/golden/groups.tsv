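sample	condition
control_001	control
control_002	control
control_003	control
control_004	control
control_005	control
control_006	control
control_007	control
control_008	control
control_009	control
control_010	control
case_001	case
case_002	case
case_003	case
case_004	case
case_005	case
case_006	case
case_007	case
case_008	case
case_009	case
case_010	case
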