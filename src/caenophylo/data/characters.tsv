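taxon	reproductive_mode	spicule_shape	blade_curvature	spicule_tip	fan_shape	fan_anterior	fan_edge	terminal_notch	ray23_space	dorsal_ray_position	short_ray4	precloacal_lip	phasmid_form	mating_position	rnai_competence
C_sp_1	gonochoristic	short_stout	bent_angle	complex	open_narrow	open	smooth	absent	large	pos5	absent	no_hook	pore	parallel	?
C_plicata	gonochoristic	long_slender	bent_angle	complex	open_narrow	open	smooth	absent	large	pos4	absent	no_hook	pore	parallel	incompetent
C_elegans	hermaphroditic	long_slender	evenly_curved	simple	heart	closed	serrated	present	small	pos5	absent	hook	pore	parallel	competent
C_remanei	gonochoristic	long_slender	evenly_curved	simple	heart	closed	serrated	present	small	pos5	absent	hook	pore	parallel	incompetent
C_sp_5	gonochoristic	long_slender	evenly_curved	simple	heart	closed	serrated	present	small	pos5	absent	hook	pore	parallel	incompetent
C_briggsae	hermaphroditic	long_slender	evenly_curved	simple	heart	closed	serrated	present	small	pos5	absent	hook	pore	parallel	incompetent
C_sp_9	gonochoristic	long_slender	evenly_curved	simple	heart	closed	serrated	present	small	pos5	absent	hook	pore	parallel	incompetent
C_brenneri	gonochoristic	long_slender	evenly_curved	simple	heart	closed	serrated	present	small	pos5	absent	hook	pore	parallel	incompetent
C_sp_11	hermaphroditic	long_slender	evenly_curved	simple	heart	closed	serrated	present	small	pos5	absent	hook	pore	parallel	incompetent
C_sp_10	gonochoristic	long_slender	evenly_curved	simple	heart	closed	serrated	present	small	pos5	absent	hook	pore	parallel	incompetent
C_sp_16	gonochoristic	long_slender	evenly_curved	simple	heart	closed	serrated	present	small	pos5	absent	hook	pore	parallel	incompetent
C_sp_15	gonochoristic	long_slender	bent_angle	simple	heart	closed	serrated	present	small	pos5	absent	hook	pore	parallel	competent
C_sp_7	gonochoristic	long_slender	bent_angle	complex	heart	closed	serrated	present	small	pos5	absent	hook	pore	parallel	competent
C_japonica	gonochoristic	long_slender	bent_angle	complex	heart	closed	serrated	present	small	pos5	present	hook	pore	parallel	competent
C_sp_14	gonochoristic	long_slender	evenly_curved	simple	heart	closed	serrated	present	small	pos5	present	hook	pore	parallel	competent
C_sp_17	gonochoristic	long_slender	bent_angle	simple	heart	closed	serrated	present	small	pos5	present	hook	pore	parallel	incompetent
C_sp_18	gonochoristic	long_slender	bent_angle	simple	heart	closed	serrated	present	small	pos5	absent	hook	pore	parallel	incompetent
C_sp_19	gonochoristic	long_slender	bent_angle	simple	heart	closed	serrated	present	small	pos5	present	hook	pore	parallel	incompetent
C_sp_20	gonochoristic	long_slender	bent_angle	complex	heart	closed	serrated	absent	large	pos4	absent	hook	pore	parallel	competent
C_sp_6	gonochoristic	long_slender	bent_angle	complex	heart	closed	serrated	absent	large	pos4	absent	hook	pore	parallel	competent
C_sp_13	gonochoristic	long_slender	bent_angle	complex	squarish	closed	serrated	absent	large	pos4	absent	no_hook	pore	parallel	competent
C_drosophilae	gonochoristic	short_stout	bent_angle	complex	open_narrow	open	smooth	absent	large	pos4	absent	no_hook	pore	parallel	incompetent
C_sp_2	gonochoristic	short_stout	bent_angle	complex	open_narrow	open	smooth	absent	large	pos4	absent	no_hook	pore	parallel	incompetent
C_sp_8	gonochoristic	short_stout	bent_angle	complex	open_narrow	open	smooth	absent	large	pos4	absent	no_hook	papilliform	spiral	incompetent
C_angaria	gonochoristic	short_stout	bent_angle	complex	open_narrow	open	smooth	absent	large	pos4	absent	no_hook	papilliform	spiral	incompetent
C_sp_12	gonochoristic	short_stout	bent_angle	complex	open_narrow	open	smooth	absent	large	pos4	absent	no_hook	papilliform	spiral	incompetent
Protorhabditis_sp	gonochoristic	short_stout	bent_angle	complex	open_narrow	open	smooth	absent	large	pos5	absent	no_hook	pore	parallel	?
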