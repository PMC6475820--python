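# Demonstration recipe->ingredient map.
# Format: recipe_id<TAB>synonym...<TAB>|<TAB>ingredient...
# The recipe id (underscores read as spaces) is implicitly its own synonym.
gluten_free_pie_crust	gf pie crust	|	rice flour	potato starch flour	xanthan gum	shortening	white sugar
gluten_free_pumpkin_bread	gf pumpkin bread	|	brown rice flour	potato starch flour	xanthan gum	pumpkin	white sugar
gluten_free_banana_bread	gf banana bread	|	white rice flour	banana	xanthan gum	white sugar	ground walnuts
gluten_free_peanut_butter_cookies	gf peanut butter cookies	|	peanut butter	soy flour	white sugar	xanthan gum
gluten_free_chocolate_chip_cookies	gf chocolate chip cookies	|	bean flour	chocolate chips	xanthan gum	shortening	white sugar
gluten_free_pancakes	gf pancakes	|	rice flour	bean flour	xanthan gum	eggs	milk
gluten_free_pizza_crust	gf pizza crust	|	brown rice flour	potato starch flour	xanthan gum	yeast
gluten_free_muffins	gf muffins	|	white rice flour	soy flour	xanthan gum	white sugar
gluten_free_bread	gf bread	|	brown rice flour	potato starch flour	xanthan gum	yeast	eggs
gluten_free_brownies	gf brownies	|	bean flour	cocoa	shortening	white sugar	ground walnuts
roasted_pumpkin_seeds	toasted pumpkin seeds	|	pumpkin seeds	olive oil	salt
pumpkin_soup	creamy pumpkin soup	|	pumpkin	cream	onion	salt
cinnamon_rolls	cinnamon buns	|	all purpose flour	cinnamon	white sugar	yeast	eggs
pumpkin_muffins	pumpkin spice muffins	|	all purpose flour	pumpkin	cinnamon	white sugar	eggs
honey_cake	jewish honey cake	|	all purpose flour	honey	dark rum	white sugar	eggs
earthquake_cake	|	all purpose flour	cocoa	cream cheese	shortening	white sugar
cucumber_salad	creamy cucumber salad	|	cucumber	pickles	vinegar	white sugar
egg_salad	classic egg salad	|	eggs	mayonnaise	pickles	mustard
pasta_salad	italian pasta salad	|	pasta	serrano chile	olives	vinegar
broccoli_salad	|	broccoli	sunflower seeds	mayonnaise	cherry	white sugar
fish_tacos	baja fish tacos	|	fish	all purpose flour	serrano chile	cabbage
ratatouille	|	eggplant	zucchini	tomato	serrano chile	olive oil
tomato_pie	southern tomato pie	|	all purpose flour	tomato	mayonnaise	cheese
tuna_noodle_casserole	|	pasta	tuna	all purpose flour	cream	peas
rum_punch	caribbean rum punch	|	dark rum	gin	peach schnapps	anisette	cherry
fruit_gelatin_mold	gelatin fruit salad	|	gelatin	cherry	peach schnapps	white sugar
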